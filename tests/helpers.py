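"""Shared report constructors for tests (no dependence on the generator module)."""

from ddisignal import Causality, Report, Sex


def make_report(i, drugs, aes, sex=Sex.FEMALE, age=65.0, year=2018,
                causality=Causality.POSSIBLE, diseases=("CVD",), soc=()):
    return Report(
        report_id=f"R{i}",
        year=year,
        age=age,
        sex=sex,
        reporter_category="hospital",
        diseases=frozenset(diseases),
        drugs=frozenset(drugs),
        aes=frozenset(aes),
        causality=causality,
        ae_soc=tuple(soc),
    )


def random_reports(rng, n, n_drugs=6, n_aes=5):
    """Random multi-drug multi-AE reports built directly, for oracle checks."""
    drug_pool = [f"D{i}" for i in range(n_drugs)]
    ae_pool = [f"A{i}" for i in range(n_aes)]
    sexes = [Sex.MALE, Sex.FEMALE, Sex.UNKNOWN]
    reports = []
    for i in range(n):
        drugs = rng.choice(drug_pool, size=int(rng.integers(1, 4)), replace=False)
        aes = rng.choice(ae_pool, size=int(rng.integers(1, 4)), replace=False)
        age = float(rng.integers(20, 95)) if rng.random() > 0.05 else None
        reports.append(make_report(
            i, drugs, aes,
            sex=sexes[int(rng.integers(0, 3))],
            age=age,
            year=int(rng.integers(2014, 2023)),
        ))
    return reports
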