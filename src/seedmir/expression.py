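"""TPM normalisation, differential calling, expression correlation, clustering
and the efficiency-corrected RT-PCR (Pfaffl) ratio.

TPM here is reads-per-million-clean-reads: count / clean_total x 1e6. A row is
called differentially expressed when, after dividing by its own maximum, its
normalised value drops below 0.5 in some library (equivalently the max/min
ratio exceeds 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import CountTable

DETECTION_TPM = 1.0
DIFFERENTIAL_CUTOFF = 0.5
LOG2_PSEUDOCOUNT = 1.0
EFFICIENCY_WINDOW = (1.8, 2.05)


def compute_tpm(counts: CountTable) -> pd.DataFrame:
    """Reads per million clean reads, rows = sequences, columns = libraries."""
    totals = np.asarray(counts.clean_totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("clean totals must be positive")
    df = counts.to_frame().astype(float)
    return df / totals * 1e6


def log2_matrix(m: pd.DataFrame, pseudocount: float = LOG2_PSEUDOCOUNT) -> pd.DataFrame:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(m + pseudocount)


def max_normalize(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each row by its own maximum. All-zero rows stay zero and are
    flagged in the returned boolean Series."""
    row_max = m.max(axis=1)
    zero = row_max == 0
    norm = m.div(row_max.where(~zero, 1.0), axis=0)
    return norm, zero


@dataclass
class DifferentialCall:
    id: str
    normalized: np.ndarray
    is_differential: bool
    max_library: str


def call_differential(tpm: pd.DataFrame,
                      detection_threshold: float = DETECTION_TPM,
                      cutoff: float = DIFFERENTIAL_CUTOFF) -> pd.DataFrame:
    """Differential flags for rows detected (TPM >= threshold) in >=1 library.

    is_differential = (min of max-normalised profile) < cutoff.
    """
    detected = tpm[(tpm >= detection_threshold).any(axis=1)]
    norm, zero = max_normalize(detected)
    calls = pd.DataFrame({
        "id": detected.index,
        "is_differential": (norm.min(axis=1) < cutoff) & ~zero,
        "max_library": detected.idxmax(axis=1),
    }).set_index("id")
    return pd.concat([norm, calls], axis=1)


def correlate_pairs(mirna_profile: np.ndarray, target_profile: np.ndarray,
                    fold_threshold: float = 2.0,
                    corr_threshold: float = -0.5) -> tuple[float, bool]:
    """Pearson correlation of two profiles and the inverse-pair flag:
    both fold-changes (max/min) > fold_threshold and r < corr_threshold."""
    a = np.asarray(mirna_profile, dtype=float)
    b = np.asarray(target_profile, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must cover identical library sets")
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, False
    r = float(np.corrcoef(a, b)[0, 1])

    def fold(x: np.ndarray) -> float:
        mn = x.min()
        return np.inf if mn == 0 else x.max() / mn

    flagged = fold(a) > fold_threshold and fold(b) > fold_threshold and r < corr_threshold
    return r, flagged


@dataclass
class QpcrMeasurement:
    target_id: str
    e_target: float
    e_ref: float
    dct_target: float  # threshold-cycle difference, control - sample
    dct_ref: float

    def __post_init__(self):
        for e in (self.e_target, self.e_ref):
            if not (1.0 < e < 3.0):
                raise ValueError(f"amplification efficiency {e} outside (1, 3)")

    @property
    def efficiency_ok(self) -> bool:
        lo, hi = EFFICIENCY_WINDOW
        return lo <= self.e_target <= hi and lo <= self.e_ref <= hi


def pfaffl_ratio(q: QpcrMeasurement) -> float:
    """Efficiency-corrected relative expression:
    E_target^dCt_target / E_ref^dCt_ref. Equals 2^ddCt when both E = 2."""
    return q.e_target ** q.dct_target / q.e_ref ** q.dct_ref


def cluster_and_project(log2m: pd.DataFrame, n_components: int = 2) -> dict:
    """Average-linkage Euclidean clustering of rows and columns, plus PCA of
    the column profiles (deterministic SVD)."""
    if log2m.shape[0] < 2 or log2m.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    X = log2m.to_numpy(dtype=float)
    col_link = hierarchy.linkage(pdist(X.T, metric="euclidean"), method="average")
    row_link = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    col_order = [log2m.columns[i] for i in hierarchy.leaves_list(col_link)]
    row_order = [log2m.index[i] for i in hierarchy.leaves_list(row_link)]

    profiles = X.T - X.T.mean(axis=0)  # columns are observations
    u, s, vt = np.linalg.svd(profiles, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for k in range(vt.shape[0]):
        imax = np.argmax(np.abs(vt[k]))
        if vt[k, imax] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u * s
    var = s ** 2
    share = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, coords.shape[1])
    return {
        "column_order": col_order,
        "row_order": row_order,
        "column_linkage": col_link,
        "row_linkage": row_link,
        "pca_coordinates": pd.DataFrame(
            coords[:, :k], index=log2m.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        "variance_share": share,
    }
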