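"""Alpha and beta diversity of OTU count tables.

The unit of computation is an :class:`OtuTable`: a samples x OTUs matrix of
non-negative integer counts with per-sample metadata (particle fraction,
depth, replicate).  All estimators are implemented from first principles on
that table:

* rarefaction — multivariate hypergeometric subsampling without replacement
  to a common library size;
* observed richness and the bias-corrected Chao1 estimator;
* Shannon entropy (natural log) and the Gini-Simpson index;
* Bray-Curtis dissimilarity between samples;
* Kruskal non-metric multidimensional scaling (NMDS) in two dimensions,
  alternating pool-adjacent-violators monotone regression with a Guttman
  configuration update, best of several seeded restarts;
* family-level relative-abundance summaries (top-k families + "other");
* shared-OTU (Jaccard) percentages and the core microbiome across groups.

Scientific-python equivalents of the scalar estimators exist elsewhere and
are used in the test-suite as independent oracles; the implementations here
are the package's own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "DissimilarityMatrix",
    "NmdsResult",
    "rarefy",
    "observed_richness",
    "chao1",
    "shannon",
    "simpson",
    "alpha_diversity",
    "bray_curtis",
    "nmds",
    "family_summary",
    "shared_otus",
    "core_microbiome",
    "sequence_retention_percent",
]

METADATA_COLUMNS = ("fraction", "depth_m", "replicate")


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with per-sample metadata.

    ``counts`` is indexed by sample id with OTU ids as columns;
    ``metadata`` is indexed by sample id and must cover every sample with at
    least the columns ``fraction``, ``depth_m`` and ``replicate``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids in count table")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate OTU ids in count table")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("OTU counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("OTU counts must be >= 0")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing for samples: {list(missing)[:5]}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata must contain a {col!r} column")
        self.metadata = self.metadata.loc[self.counts.index]

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "OtuTable":
        ids = list(sample_ids)
        return OtuTable(self.counts.loc[ids].copy(), self.metadata.loc[ids].copy())

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return OtuTable(self.counts[keep].copy(), self.metadata.copy())


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric dissimilarity matrix in [0, 1] with a zero diagonal."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-9:
            raise ValueError("dissimilarities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class NmdsResult:
    """Best-of-restarts NMDS solution with its Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    n_iterations: int
    converged: bool
    seed: int
    n_restarts: int
    ids: tuple[str, ...] = ()
    stress_history: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity
# ---------------------------------------------------------------------------


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to a common library size.

    ``depth`` defaults to the smallest sample total.  Each sample is drawn
    from the multivariate hypergeometric distribution over its OTU counts, so
    expected per-OTU proportions are preserved.
    """
    sums = table.sample_sums().to_numpy()
    min_total = int(sums.min())
    if depth is None:
        depth = min_total
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be > 0")
    if depth > min_total:
        raise ValueError(
            f"rarefaction depth {depth} exceeds the smallest library ({min_total})"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    frame = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(frame, table.metadata.copy())


def observed_richness(table: OtuTable) -> pd.Series:
    """Number of OTUs with count > 0 per sample."""
    return (table.counts > 0).sum(axis=1).rename("observed")


def chao1(table: OtuTable) -> pd.Series:
    """Bias-corrected Chao1 richness estimate per sample.

    S_chao1 = S_obs + f1*(f1-1) / (2*(f2+1)) with f1 singletons and f2
    doubletons; the bias-corrected form stays finite when no doubletons are
    observed and equals S_obs whenever f1 <= 1.
    """
    counts = table.counts.to_numpy()
    s_obs = (counts > 0).sum(axis=1)
    f1 = (counts == 1).sum(axis=1)
    f2 = (counts == 2).sum(axis=1)
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return pd.Series(est, index=table.counts.index, name="chao1")


def _proportions(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("cannot compute diversity of an empty sample")
    return counts / totals


def shannon(table: OtuTable, base: float | None = None) -> pd.Series:
    """Shannon entropy H = -sum p_i ln p_i per sample (nats by default)."""
    p = _proportions(table.counts.to_numpy().astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    if base is not None:
        h = h / np.log(base)
    return pd.Series(h, index=table.counts.index, name="shannon")


def simpson(table: OtuTable, kind: str = "gini") -> pd.Series:
    """Simpson diversity per sample.

    ``kind='gini'`` returns the Gini-Simpson index 1 - sum p_i^2 (the
    probability that two random reads belong to different OTUs);
    ``kind='inverse'`` returns 1 / sum p_i^2.
    """
    p = _proportions(table.counts.to_numpy().astype(float))
    d = (p**2).sum(axis=1)
    if kind == "gini":
        out = 1.0 - d
    elif kind == "inverse":
        out = 1.0 / d
    else:
        raise ValueError("kind must be 'gini' or 'inverse'")
    return pd.Series(out, index=table.counts.index, name="simpson")


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Observed richness, Chao1, Shannon (nats) and Gini-Simpson per sample."""
    return pd.concat(
        [observed_richness(table), chao1(table), shannon(table), simpson(table)],
        axis=1,
    )


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: OtuTable) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y) between samples.

    Computed on the (typically rarefied) count table.  A pair of two all-zero
    samples is defined as 0 with a warning.
    """
    x = table.counts.to_numpy().astype(float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    d = np.zeros((n, n))
    warned = False
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        zero = den == 0
        if zero.any() and not warned:
            warnings.warn(
                "pair of all-zero samples: Bray-Curtis defined as 0", stacklevel=2
            )
            warned = True
        vals = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
        d[i, i + 1 :] = vals
        d[i + 1 :, i] = vals
    return DissimilarityMatrix(values=d, ids=tuple(table.counts.index))


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling
# ---------------------------------------------------------------------------


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit to y."""
    values: list[float] = []
    weights: list[int] = []
    for v in y:
        values.append(float(v))
        weights.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            w = weights[-1] + weights[-2]
            merged = (values[-1] * weights[-1] + values[-2] * weights[-2]) / w
            values.pop()
            weights.pop()
            values[-1] = merged
            weights[-1] = w
    out = np.empty(len(y), dtype=float)
    pos = 0
    for v, w in zip(values, weights):
        out[pos : pos + w] = v
        pos += w
    return out


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling used as the first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    d: DissimilarityMatrix | np.ndarray,
    n_components: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsResult:
    """Kruskal non-metric MDS of a dissimilarity matrix.

    Each run alternates (a) monotone regression (pool-adjacent-violators,
    primary/weak tie treatment: tied dissimilarities are ordered by the
    current configuration distances) of the configuration distances on the
    dissimilarity ranks and (b) a Guttman-transform configuration update with
    the fitted disparities.  The objective is Kruskal stress-1::

        stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 )

    Accepted iterations never increase stress (a worsening update is rolled
    back and the run stops).  The first start is a classical-scaling
    configuration, the remaining ``n_restarts - 1`` are random; the solution
    with the lowest final stress is returned.
    """
    if isinstance(d, DissimilarityMatrix):
        ids = d.ids
        mat = d.values
    else:
        mat = np.asarray(d, dtype=float)
        ids = tuple(str(i) for i in range(mat.shape[0]))
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("NMDS input must be a square symmetric matrix")
    n = mat.shape[0]
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 objects")
    iu = np.triu_indices(n, 1)
    diss = mat[iu]
    scale = diss.mean() if diss.mean() > 0 else 1.0
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x = _classical_scaling(mat, n_components)
        else:
            x = rng.uniform(-scale, scale, size=(n, n_components))
        history: list[float] = []
        converged = False
        prev_stress = np.inf
        prev_x = x
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            dist = np.sqrt((diff**2).sum(axis=-1))
            dv = dist[iu]
            order = np.lexsort((dv, diss))
            dhat = np.empty_like(dv)
            dhat[order] = _pava(dv[order])
            denom = (dv**2).sum()
            stress = float(np.sqrt(((dv - dhat) ** 2).sum() / denom)) if denom > 0 else 0.0
            if stress > prev_stress + 1e-12:
                x = prev_x  # roll back the worsening update and stop
                break
            history.append(stress)
            if prev_stress - stress < tol * max(prev_stress, 1e-30):
                converged = True
                break
            prev_stress = stress
            prev_x = x
            # Guttman transform with the disparities
            full = np.zeros((n, n))
            full[iu] = dhat
            full += full.T
            safe = np.where(dist > 0, dist, 1.0)
            ratio = np.where(dist > 0, full / safe, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = b @ x / n
            x -= x.mean(axis=0)
        final = history[-1] if history else np.inf
        if best is None or final < best[0]:
            best = (final, x - x.mean(axis=0), history, converged)

    assert best is not None
    stress, coords, history, converged = best
    return NmdsResult(
        coordinates=coords,
        stress=stress,
        n_iterations=len(history),
        converged=converged,
        seed=seed,
        n_restarts=n_restarts,
        ids=ids,
        stress_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# taxonomy summaries and shared-OTU statistics
# ---------------------------------------------------------------------------


def family_summary(
    table: OtuTable, taxonomy: pd.DataFrame, k: int = 20
) -> pd.DataFrame:
    """Per-sample relative abundance of the k most abundant families + "other".

    Families are ranked by mean relative abundance across all samples; OTUs
    without a family assignment are pooled under "Unassigned".  Each row of
    the result sums to 1.
    """
    fam = taxonomy["family"] if "family" in taxonomy.columns else taxonomy.iloc[:, 0]
    labels = [str(fam.get(otu, "Unassigned")) for otu in table.counts.columns]
    rel = table.counts.div(table.sample_sums(), axis=0)
    by_family = rel.T.groupby(pd.Index(labels, name="family")).sum().T
    top = by_family.mean(axis=0).sort_values(ascending=False).index[:k]
    summary = by_family[list(top)].copy()
    summary["other"] = by_family.drop(columns=list(top)).sum(axis=1)
    return summary


def _pooled_presence(table: OtuTable, sample_ids) -> set[str]:
    ids = list(sample_ids)
    if not ids:
        raise ValueError("sample group must be non-empty")
    sub = table.counts.loc[ids]
    present = sub.columns[(sub > 0).any(axis=0)]
    return set(present)


def shared_otus(table: OtuTable, group_a, group_b) -> float:
    """Percentage of OTUs shared between two pooled sample groups.

    Presence is pooled within each group (an OTU is present if any member
    sample has a count > 0); the statistic is 100 * |A & B| / |A | B|.
    """
    a_ids, b_ids = set(group_a), set(group_b)
    if a_ids & b_ids:
        raise ValueError("sample groups must be disjoint")
    a = _pooled_presence(table, group_a)
    b = _pooled_presence(table, group_b)
    union = a | b
    if not union:
        warnings.warn("both groups contain no OTUs; shared percentage set to 0")
        return 0.0
    return 100.0 * len(a & b) / len(union)


def core_microbiome(table: OtuTable, groups) -> list[str]:
    """OTUs present (pooled presence) in every one of >= 2 sample groups."""
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sets = [_pooled_presence(table, g) for g in groups]
    core = set.intersection(*sets)
    return sorted(core)


def sequence_retention_percent(retained: int, total: int) -> float:
    """Percentage of raw sequences retained after read pre-processing."""
    if total <= 0:
        raise ValueError("total sequence count must be > 0")
    if not 0 <= retained <= total:
        raise ValueError("retained count must be between 0 and total")
    return 100.0 * retained / total
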