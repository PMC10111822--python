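import matplotlib
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_screen_df():
    """Three genes x three hairpins with hand-picked counts."""
    return pd.DataFrame(
        {
            "hairpin_id": [f"{g}_h{i}" for g in ("A", "B", "C") for i in (1, 2, 3)],
            "gene_id": [g for g in ("A", "B", "C") for _ in range(3)],
            "count_day0": [100, 100, 100, 100, 100, 100, 100, 100, 100],
            "count_day14": [500, 450, 90, 210, 90, 80, 100, 100, 100],
        }
    )


@pytest.fixture
def cohort_cores_df():
    """Four tumours, duplicate cores, mixed receptor status."""
    rows = []
    spec = [
        # tumour, cores (I, A), er, her2, ki67, tubule
        ("T1", [(3, 90.0), (2, 40.0)], "pos", "neg", 10.0, 1),
        ("T2", [(0, 0.0), (0, 0.0)], "neg", "neg", 40.0, 3),
        ("T3", [(1, 30.0), (2, 80.0)], "pos", "pos", 25.0, 2),
        ("T4", [(2, 30.0), (1, 10.0)], "neg", "pos", 30.0, 3),
    ]
    for tid, cores, er, her2, ki67, tub in spec:
        for cid, (i, a) in enumerate(cores, start=1):
            rows.append(
                {
                    "tumour_id": tid,
                    "core_id": cid,
                    "intensity": i,
                    "area_pct": a,
                    "er_status": er,
                    "her2_status": her2,
                    "ki67_pct": ki67,
                    "grade": 2,
                    "mitotic_score": 1,
                    "tubule_score": tub,
                    "histotype": "IC (NST)",
                    "stage": "II",
                    "age_dx": 55.0,
                    "surv_years": 5.0,
                    "event": 0,
                }
            )
    return pd.DataFrame(rows)
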