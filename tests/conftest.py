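import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fosnet.network import CorrelationResult, r_to_t
from fosnet.registries import RegionRegistry
from scipy import stats

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

REGIONS = RegionRegistry().regions

#: Printed emitter tally being emulated by the per-animal USV fixture:
#: condition -> {(emitter_class, sex): count}; row totals 8 / 19 / 24.
PUBLISHED_EMITTER_TALLY = {
    "COT": {("only22", "F"): 2, ("only22", "M"): 0, ("both", "F"): 3, ("both", "M"): 0,
            ("only55", "F"): 1, ("only55", "M"): 2},
    "BOT": {("only22", "F"): 3, ("only22", "M"): 1, ("both", "F"): 1, ("both", "M"): 1,
            ("only55", "F"): 6, ("only55", "M"): 7},
    "BLT": {("only22", "F"): 7, ("only22", "M"): 2, ("both", "F"): 6, ("both", "M"): 3,
            ("only55", "F"): 2, ("only55", "M"): 4},
}


def make_fos_frame(arrays_by_condition, regions=None):
    """Long-format Fos frame from {condition: subjects x regions array};
    sexes alternate F, M."""
    regions = list(regions if regions is not None else REGIONS)
    rows = []
    for cond, arr in arrays_by_condition.items():
        arr = np.asarray(arr, dtype=float)
        for i in range(arr.shape[0]):
            for j, region in enumerate(regions):
                rows.append(
                    {
                        "subject_id": f"{cond}{i + 1:02d}",
                        "sex": ("F", "M")[i % 2],
                        "condition": cond,
                        "region": region,
                        "fos_count": arr[i, j],
                    }
                )
    return pd.DataFrame(rows)


def correlation_result_from_r(r_by_pair, n, regions, condition="X"):
    """Hand-built CorrelationResult with constant per-pair n.

    ``r_by_pair`` maps (region_a, region_b) -> r; unspecified pairs get 0.
    p-values follow the t re-test so the object is internally consistent.
    """
    k = len(regions)
    r = np.zeros((k, k))
    np.fill_diagonal(r, np.nan)
    for (a, b), val in r_by_pair.items():
        i, j = regions.index(a), regions.index(b)
        r[i, j] = r[j, i] = val
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            t, df = r_to_t(r[i, j], n)
            pij = 0.0 if math.isinf(t) else 2 * stats.t.sf(abs(t), df)
            p[i, j] = p[j, i] = pij
    idx = list(regions)
    return CorrelationResult(
        condition=condition,
        regions=tuple(regions),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(np.full((k, k), n, dtype=int), index=idx, columns=idx),
        missing=pd.DataFrame(np.zeros((k, k), dtype=bool), index=idx, columns=idx),
    )


def usv_fixture_frame():
    """Per-animal USV minute counts whose block scores reproduce the
    published emitter tally exactly (synthetic reconstruction: per-animal
    call counts are not published, only the tally)."""
    rows = []
    counter = 0
    emits55 = {"only55": True, "both": True, "only22": False}
    emits22 = {"only55": False, "both": True, "only22": True}
    for cond, cells in PUBLISHED_EMITTER_TALLY.items():
        for (cls, sex), count in cells.items():
            for _ in range(count):
                counter += 1
                c55 = [11, 12] + [0] * 8 if emits55[cls] else [0] * 10
                c22 = [2] + [0] * 9 if emits22[cls] else [0] * 10
                row = {"subject_id": f"U{counter:03d}", "sex": sex, "condition": cond}
                row.update({f"khz55_min_{m + 1}": c55[m] for m in range(10)})
                row.update({f"khz22_min_{m + 1}": c22[m] for m in range(10)})
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def usv_fixture():
    return usv_fixture_frame()
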