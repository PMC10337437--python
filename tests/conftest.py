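import pytest

import carecascade as cc
from carecascade.types import GeneratorParams


@pytest.fixture(scope="session")
def paper_spec():
    return cc.paper_fixture_spec()


@pytest.fixture(scope="session")
def paper_df(paper_spec):
    """Deterministic fixture dataset with wealth quintiles attached."""
    return cc.attach_wealth_quintile(cc.reconstruct_fixture(paper_spec))


@pytest.fixture(scope="session")
def sim_df():
    """A mid-sized simulated survey (default planted effects), quintiles on."""
    params = GeneratorParams(n_per_setting=2000, seed=20260926)
    return cc.attach_wealth_quintile(cc.generate_population(params))


def brute_force_cascade(df, fbg_threshold=126.0, case_thr=6.5, ctrl_thr=8.0):
    """Independent per-record filter-and-count oracle for the cascade."""
    import math

    def present(v):
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    counts = dict.fromkeys(
        ["cases", "tested", "diagnosed", "in_care", "in_treatment",
         "under_control", "advice", "undiagnosed"], 0)
    for _, row in df.iterrows():
        drugs = bool(row["takes_t2d_drugs"]) or bool(row["takes_insulin"])
        bio = (present(row["fbg_mg_dl"]) and present(row["hba1c_pct"])
               and row["fbg_mg_dl"] >= fbg_threshold
               and row["hba1c_pct"] >= case_thr)
        if not (bio or drugs):
            continue
        counts["cases"] += 1
        if not bool(row["ever_told_t2d"]):
            counts["undiagnosed"] += 1
        if not bool(row["ever_tested_3y"]):
            continue
        counts["tested"] += 1
        if not bool(row["ever_told_t2d"]):
            continue
        counts["diagnosed"] += 1
        if not bool(row["care_past_12m"]):
            continue
        counts["in_care"] += 1
        if not drugs:
            continue
        counts["in_treatment"] += 1
        if all(bool(row[c]) for c in ("advice_diet", "advice_weight",
                                      "advice_smoking", "advice_exercise")):
            counts["advice"] += 1
        if present(row["hba1c_pct"]) and row["hba1c_pct"] < ctrl_thr:
            counts["under_control"] += 1
    return counts
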