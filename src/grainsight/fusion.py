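"""Maximum-correlation feature fusion across two views.

Given two feature matrices extracted from different backbones, the fused
matrix keeps one representative of every near-duplicate column pair and
drops columns that no column of the *other* view corroborates:

* R1 (redundancy) — scanning the concatenated columns in order, a column
  is dropped when its absolute correlation with a still-kept earlier
  column reaches ``tau_high`` (near-duplicates carry no new information;
  the earlier column wins ties).
* R2 (corroboration) — a surviving column is dropped when its maximum
  absolute correlation against every column of the other view is at most
  ``tau_low`` (a feature no second view echoes is treated as view noise).

The default association measure is the absolute Pearson coefficient; a
binned maximal-correlation estimator (the supremum of correlations over
Borel transforms of each margin, estimated on quantile bins) is available
for nonlinear association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FusionConfig",
    "FusionReport",
    "pearson_correlation",
    "maximal_correlation_binned",
    "fuse_features",
]


@dataclass(frozen=True)
class FusionConfig:
    tau_high: float = 0.90
    tau_low: float = 0.05
    estimator: str = "pearson"  # or "maximal_binned"
    n_bins: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.tau_low < self.tau_high <= 1:
            raise ValueError("require 0 <= tau_low < tau_high <= 1")
        if self.estimator not in ("pearson", "maximal_binned"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class FusionReport:
    kept_ids: list[str] = field(default_factory=list)
    dropped_redundant: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_low: list[tuple[str, float]] = field(default_factory=list)

    @property
    def fused_dim(self) -> int:
        return len(self.kept_ids)

    def to_dict(self) -> dict:
        return {
            "kept_ids": self.kept_ids,
            "dropped_redundant": [list(t) for t in self.dropped_redundant],
            "dropped_low": [list(t) for t in self.dropped_low],
            "fused_dim": self.fused_dim,
        }


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson coefficient; 0 by definition for a constant column."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("columns must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    # rank-based binning: ties broken by position, bins near-equal in size
    order = np.argsort(x, kind="stable")
    bins = np.empty(len(x), dtype=int)
    bins[order] = (np.arange(len(x)) * n_bins) // len(x)
    return bins


def maximal_correlation_binned(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Binned maximal correlation sup_{g,h} corr(g(x), h(y)) in [0, 1].

    Both margins are discretized into near-equal quantile bins; for
    discrete variables the supremum over all transforms of each margin is
    the second singular value of the standardized contingency matrix
    Q_ij = p_ij / sqrt(p_i. p_.j) — the closed form of the alternating
    conditional-expectations fixed point, so no iteration is needed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("columns must have equal length")
    if x.size < 2 * n_bins:
        raise ValueError("need at least 2 * n_bins samples")
    bx = _quantile_bins(x, n_bins)
    by = _quantile_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = joint / np.sqrt(np.outer(px, py))
    Q = np.nan_to_num(Q)
    sv = np.linalg.svd(Q, compute_uv=False)
    # the leading singular value 1 corresponds to the constant transform
    raw = float(np.clip(sv[1] if len(sv) > 1 else 0.0, 0.0, 1.0))
    # small-sample bias correction: for independent margins the second
    # singular value of the empirical table concentrates at the
    # Marchenko-Pastur edge e = (sqrt(bx-1) + sqrt(by-1)) / sqrt(n);
    # invert the noise model sv^2 ~ cv^2 + e^2 (1 - cv^2)
    edge = 2.0 * np.sqrt(n_bins - 1) / np.sqrt(x.size)
    if edge < 1.0:
        raw = np.sqrt(max(0.0, (raw**2 - edge**2) / (1.0 - edge**2)))
    # maximal correlation dominates |Pearson| (the identity transform is
    # one admissible Borel pair), so the linear estimate is a second
    # lower bound; binning attenuation can otherwise fall below it
    return float(max(raw, abs(pearson_correlation(x, y))))


def _abs_corr_matrix(values: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    d = values.shape[1]
    if cfg.estimator == "pearson":
        sd = values.std(axis=0)
        ok = sd > 0
        corr = np.zeros((d, d))
        if ok.any():
            sub = np.corrcoef(values[:, ok], rowvar=False)
            sub = np.atleast_2d(np.nan_to_num(sub))
            corr[np.ix_(ok, ok)] = np.abs(sub)
        np.fill_diagonal(corr, 1.0)
        return corr
    corr = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            corr[i, j] = corr[j, i] = maximal_correlation_binned(
                values[:, i], values[:, j], cfg.n_bins
            )
    return corr


def fuse_features(
    F_dar: pd.DataFrame, F_squ: pd.DataFrame, cfg: FusionConfig | None = None
) -> tuple[pd.DataFrame, FusionReport]:
    """Fuse two row-aligned feature matrices by the R1 + R2 rules.

    The first view's columns precede the second's; both rules are applied
    in that column order (deterministic tie-break).  Raises on sample-id
    mismatch.
    """
    cfg = cfg or FusionConfig()
    if len(F_dar) != len(F_squ) or not F_dar.index.equals(F_squ.index):
        raise ValueError("sample_id mismatch between views")
    both = pd.concat([F_dar, F_squ], axis=1)
    if both.columns.duplicated().any():
        raise ValueError("column ids must be unique across views")
    values = both.to_numpy(dtype=float)
    columns = list(both.columns)
    n_dar = F_dar.shape[1]
    corr = _abs_corr_matrix(values, cfg)

    report = FusionReport()
    kept: list[int] = []
    for j in range(len(columns)):
        partner = next((k for k in kept if corr[j, k] >= cfg.tau_high), None)
        if partner is None:
            kept.append(j)
        else:
            report.dropped_redundant.append(
                (columns[partner], columns[j], float(corr[j, partner]))
            )

    final: list[int] = []
    for j in kept:
        other = np.arange(n_dar, len(columns)) if j < n_dar else np.arange(n_dar)
        max_r = float(corr[j, other].max()) if len(other) else 0.0
        if max_r <= cfg.tau_low:
            report.dropped_low.append((columns[j], max_r))
        else:
            final.append(j)

    report.kept_ids = [columns[j] for j in final]
    return both.iloc[:, final], report
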