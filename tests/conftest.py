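import numpy as np
import pytest

from spanmerge import CategoricalGrid, default_match_table, MergedCodeScheme

NATURAL = 6001          # synthetic natural-vegetation code (non-agricultural)
NATURAL_CDL = 152       # shrubland-like non-agricultural crop-layer code


@pytest.fixture(scope="session")
def table():
    return default_match_table()


@pytest.fixture(scope="session")
def scheme():
    return MergedCodeScheme()


def make_grid(values, **kwargs) -> CategoricalGrid:
    return CategoricalGrid(values=np.asarray(values, dtype=np.int32), **kwargs)


def random_pair(table, rng, rows, cols, ag_prob=0.5, conflict_prob=0.3):
    """Small random aligned grid pair exercising all three pixel relations."""
    nvc_ag = sorted(table.nvc_ag_set)
    cdl_ag = sorted(table.cdl_ag_set)
    nvc = np.full((rows, cols), NATURAL, dtype=np.int32)
    cdl = np.full((rows, cols), NATURAL_CDL, dtype=np.int32)
    for r in range(rows):
        for c in range(cols):
            if rng.random() < ag_prob:
                v = nvc_ag[rng.integers(len(nvc_ag))]
                nvc[r, c] = v
                if rng.random() < conflict_prob:
                    cdl[r, c] = NATURAL_CDL if rng.random() < 0.5 else cdl_ag[
                        rng.integers(len(cdl_ag))
                    ]
                else:
                    match = sorted(table.group_of(v).cdl_values)
                    cdl[r, c] = match[rng.integers(len(match))]
            else:
                if rng.random() < 0.2:
                    cdl[r, c] = cdl_ag[rng.integers(len(cdl_ag))]
    return make_grid(nvc), make_grid(cdl)


def assert_conservation(nvc, cdl, table, result):
    """The merge invariants asserted on every fixture run: untouched
    non-agricultural pixels, restricted output codomain, and closed
    pixel accounting."""
    ag = np.isin(nvc.values, list(table.nvc_ag_set))
    out = result.merged.values

    # non-agricultural vegetation passes through bit-identically
    assert np.array_equal(out[~ag], nvc.values[~ag])

    # codomain: negated crop codes, vegetation codes present in input, or -1001
    allowed = (
        {-c for c in table.cdl_ag_set}
        | set(np.unique(nvc.values[~ag]).tolist())
        | {-1001}
    )
    assert set(np.unique(out).tolist()) <= allowed

    counts = result.counts
    assert counts["matched"] + counts["mismatched"] == int(ag.sum())
    assert counts["resolved"] + counts["unresolved"] == counts["mismatched"]
    assert counts["unresolved"] <= counts["mismatched"]
    result.check_accounting()
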