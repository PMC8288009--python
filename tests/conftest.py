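import numpy as np
import pandas as pd
import pytest

from introshell import introgen, syndata

# Reconstructed per-depth Me15/16 class counts for the study-scale stock:
# columns (ME, MT, ME x MG, ME x MT), rows at 1/3/5/7 m.  The unique integer
# solution consistent with the published per-depth proportions and allele
# frequencies.
ME1516_COUNTS = {
    1.0: {"ME": 100, "MT": 0, "ME×MG": 11, "ME×MT": 7},
    3.0: {"ME": 93, "MT": 2, "ME×MG": 21, "ME×MT": 4},
    5.0: {"ME": 96, "MT": 0, "ME×MG": 18, "ME×MT": 3},
    7.0: {"ME": 69, "MT": 0, "ME×MG": 13, "ME×MT": 1},
}

# Depth-stratified SNP introgression table: per-depth n, MT_AF bin counts,
# and printed mean H_O / HI.
TABLE2 = pd.DataFrame(
    {
        "depth": [1.0, 3.0, 5.0, 7.0],
        "n": [116, 118, 118, 83],
        "LT10": [14, 15, 18, 10],
        "10_50": [2, 4, 1, 1],
        "50_75": [2, 1, 2, 0],
        "GT75": [3, 2, 1, 0],
        "H_O": [0.032, 0.035, 0.030, 0.015],
        "HI": [0.058, 0.055, 0.038, 0.016],
        "pct_mt_positive": [18.1, 18.6, 18.6, 13.3],
    }
)

_CLASS_FRAGMENTS = {
    "ME": {180},
    "MT": {168},
    "MG": {126},
    "ME×MG": {180, 126},
    "ME×MT": {180, 168},
    "MG×MT": {126, 168},
}


def me1516_calls_from_counts(counts=ME1516_COUNTS, n_undetermined=2):
    """Expand the per-depth class counts into calls + a depth map."""
    calls, depths = [], {}
    k = 0
    for depth, by_class in counts.items():
        for cls, n in by_class.items():
            for _ in range(n):
                k += 1
                ind = f"m{k:04d}"
                calls.append(introgen.call_me1516(_CLASS_FRAGMENTS[cls], ind))
                depths[ind] = depth
    for _ in range(n_undetermined):
        k += 1
        ind = f"m{k:04d}"
        calls.append(introgen.call_me1516(set(), ind))
        depths[ind] = 1.0
    return calls, depths


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale synthetic cohort (435 individuals, 33 loci, seed 7)."""
    panel = syndata.default_panel(seed=7)
    design = syndata.default_design(seed=7)
    return syndata.simulate_cohort(design, panel)


@pytest.fixture(scope="session")
def strict_cohort():
    """Small cohort on a fully strict panel: every class dosage pattern exact."""
    panel = syndata.simulate_panel(20, 20, 0.0, seed=3)
    design = syndata.CohortDesign(
        n_by_depth={1.0: 40},
        mixture={
            1.0: {
                "PURE_ME": 0.25,
                "PURE_MT": 0.25,
                "F1_ME_MT": 0.25,
                "BC_ME_MT_TO_ME": 0.125,
                "BC_ME_MT_TO_MT": 0.125,
            }
        },
        seed=3,
    )
    return syndata.simulate_cohort(design, panel)


@pytest.fixture(scope="session")
def qc_fixture():
    """65-locus, 440-individual matrix with the full QC failure ledger.

    Locus flags: 5 poor clustering, 2 false calls, 21 ambiguous; 4 further
    loci exceed 20% missing data.  Individuals: 4 flagged by QC, 1 above the
    20% missing threshold on the retained panel.
    """
    rng = np.random.default_rng(42)
    n_ind, n_loc = 440, 65
    ids = [f"i{j:03d}" for j in range(n_ind)]
    loci = [f"L{j:02d}" for j in range(1, n_loc + 1)]
    matrix = pd.DataFrame(0.0, index=ids, columns=loci)
    # sprinkle some MT signal so the fixture is not degenerate
    hot = rng.choice(n_ind, 40, replace=False)
    matrix.iloc[hot, 40:] = rng.choice([0.0, 0.5, 1.0], size=(40, 25))

    flags = pd.DataFrame(False, index=loci, columns=["cluster_fail", "false_call", "ambiguous"])
    flags.iloc[0:5, 0] = True
    flags.iloc[5:7, 1] = True
    flags.iloc[7:28, 2] = True
    # 4 unflagged loci with >20% missing calls
    for j in range(28, 32):
        rows = rng.choice(n_ind, int(0.25 * n_ind), replace=False)
        matrix.iloc[rows, j] = np.nan
    # 1 individual missing >20% of the retained (final 33) loci
    matrix.iloc[10, 32:] = np.nan
    ind_flags = pd.Series(False, index=ids)
    ind_flags.iloc[[100, 200, 300, 400]] = True
    return matrix, flags, ind_flags
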