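"""Group statistics and 2-D embedding of latent features.

Welch's unequal-variance t-test compares each latent feature between
two groups, Benjamini-Hochberg step-up adjustment converts the p-values
to q-values (FDR), and UMAP projects latent vectors to two dimensions
for cluster inspection.  The t-test and the FDR adjustment are
delegated to scipy and statsmodels respectively; the embedding to
umap-learn -- all behind stable module functions so the rest of the
package never touches those APIs directly.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass
class GroupSummary:
    """Sufficient statistics of one group: label, n, mean, sample SD (ddof=1)."""

    group_label: str
    n: int
    mean: np.ndarray | float
    sd: np.ndarray | float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.group_label!r} needs n >= 2, got {self.n}")
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_values(cls, values: Sequence[float] | np.ndarray, label: str = "") -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label, v.shape[0], v.mean(axis=0), v.std(axis=0, ddof=1))


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def _welch_from_stats(m_a, s_a, n_a, m_b, s_b, n_b) -> WelchResult:
    va, vb = s_a**2 / n_a, s_b**2 / n_b
    if va + vb == 0:
        if m_a == m_b:
            raise ValueError(
                "Welch t undefined: both groups have zero variance and equal means"
            )
        return WelchResult(np.inf if m_a > m_b else -np.inf, np.nan, 0.0)
    t, p = stats.ttest_ind_from_stats(m_a, s_a, n_a, m_b, s_b, n_b, equal_var=False)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return WelchResult(float(t), float(df), float(p))


def welch_test(a, b) -> WelchResult:
    """Welch's two-sided t-test from raw vectors or :class:`GroupSummary` pairs.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.
    """
    if isinstance(a, GroupSummary) and isinstance(b, GroupSummary):
        return _welch_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n)
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return _welch_from_stats(
        va.mean(), va.std(ddof=1), va.size, vb.mean(), vb.std(ddof=1), vb.size
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_latent_features(
    latent: pd.DataFrame,
    labels: Sequence[str],
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Welch + BH comparison of every latent column between two groups.

    Returns one row per feature, ranked by p ascending, with per-group
    mean/SD/n, the t statistic, Welch df, two-sided p and BH q.
    ``group_order`` fixes which group is reported first (and the sign of
    t); by default groups appear in sorted label order.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != len(latent):
        raise ValueError("labels must align with latent rows")
    uniq = sorted(set(labels)) if group_order is None else list(group_order)
    if len(set(labels)) != 2 or len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(set(labels))}")
    ga, gb = uniq
    A = latent.loc[labels == ga]
    B = latent.loc[labels == gb]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for col in latent.columns:
        res = welch_test(A[col].to_numpy(), B[col].to_numpy())
        rows.append(
            {
                "feature": col,
                f"mean_{ga}": A[col].mean(), f"sd_{ga}": A[col].std(ddof=1),
                f"n_{ga}": len(A),
                f"mean_{gb}": B[col].mean(), f"sd_{gb}": B[col].std(ddof=1),
                f"n_{gb}": len(B),
                "t": res.t, "df": res.df, "p": res.p,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def format_feature_table(table: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Render a comparison table in 'mean +/- SD' layout with p and q."""
    mean_cols = [c for c in table.columns if c.startswith("mean_")]
    out = pd.DataFrame({"feature": table["feature"]})
    for mc in mean_cols:
        g = mc[len("mean_"):]
        out[g] = [
            f"{m:.{digits}f} ± {s:.{digits}f}"
            for m, s in zip(table[mc], table[f"sd_{g}"])
        ]
    out["p"] = [f"{p:.3g}" for p in table["p"]]
    out["q"] = [f"{q:.3g}" for q in table["q"]]
    return out


@dataclasses.dataclass
class Embedding2D:
    coordinates: np.ndarray  # n x 2
    n_neighbors: int
    min_dist: float
    metric: str
    seed: int

    def to_frame(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=["UMAP1", "UMAP2"])
        if sample_ids is not None:
            df.insert(0, "sample_id", list(sample_ids))
        return df


def embed_2d(
    latent,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 0,
) -> Embedding2D:
    """Seeded 2-D UMAP embedding of the latent matrix."""
    X = latent.to_numpy(dtype=float) if isinstance(latent, pd.DataFrame) else np.asarray(
        latent, dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {n_neighbors + 1} samples, got {X.shape[0]}"
        )
    import umap  # deferred: slow import

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        metric=metric, random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(X), dtype=float)
    return Embedding2D(coords, n_neighbors, min_dist, metric, seed)
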