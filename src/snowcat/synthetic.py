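"""Seeded synthetic datasets with the statistical structure of an MSC study.

The generator emulates a mesopelagic particle-fraction survey: 36 samples =
3 fraction types (Niskin water, MSC non-sinking top, MSC fast-sinking plate)
x 4 depths (28, 70, 128, 500 m) x 3 replicates.  The default scenario is
calibrated so that

* observed richness on fast-sinking particles collapses from 314 OTUs at
  28 m to 128 at 500 m while the non-sinking fraction rises from 262 to 531;
* the deep fast-sinking community is dominated by two copiotrophic genera
  (*Acinetobacter* and *Pseudomonas*, two OTUs each) summing to 92% of reads
  at 500 m (57% at 128 m);
* the OTU overlap (pooled-presence Jaccard percentage) between the fast- and
  non-sinking fractions decays from ~53% at 28 m to ~16% at 500 m;
* leucine uptake and cell concentrations reproduce the magnitude and depth
  decay of the measured rate profiles, with lognormal triplicate noise.

Interior-depth targets (70 and 128 m) are interpolations between the surface
and 500 m anchors and are synthetic, not measured, values.

Community model
---------------
Within each (fraction, depth) cell the non-dominant community follows a
geometric rank-abundance series with decay parameter ``rank_abundance_shape``
(theta): the i-th ranked OTU has relative abundance proportional to
``(1 - theta)**(i - 1)``.  Counts are multinomial draws of ``library_size``
reads per sample (optionally Dirichlet-overdispersed).  Because rare OTUs
escape detection at finite library size, the series truncation S is solved so
that the *expected number of detected OTUs* in one sample equals the
richness target; likewise the number of OTUs shared between the fast and
non-sinking identity pools is solved so that the *expected observed* pooled
Jaccard percentage matches the overlap target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import OtuTable, observed_richness, shared_otus
from .msc import MscGeometry

__all__ = [
    "FRACTIONS",
    "DEPTHS_M",
    "DEFAULT_LIBRARY_SIZE",
    "CommunityCell",
    "CommunityScenario",
    "RateCell",
    "RateScenario",
    "SyntheticDataset",
    "default_scenario",
    "generate_otu_table",
    "generate_rates",
    "plate_measurements",
    "generate_reference_profile",
    "simulate_dataset",
    "calibration_summary",
    "sample_id",
]

FRACTIONS = ("niskin", "nonsink", "fast")
DEPTHS_M = (28, 70, 128, 500)
N_REPLICATES = 3
#: Reads per sample; order of magnitude of retained amplicon reads per sample.
DEFAULT_LIBRARY_SIZE = 20_000
#: Size of the regional OTU pool identities are drawn from.  Sized so the
#: union of all per-depth pools lands near one thousand distinct OTUs.
GLOBAL_POOL_SIZE = 1100

#: Reserved ids for the deep fast-sinking dominants: two OTUs per genus.
DOMINANT_OTUS: dict[str, list[tuple[str, str, str]]] = {
    "Acinetobacter": [
        ("OTU_dom_Acin1", "Moraxellaceae", "Acinetobacter"),
        ("OTU_dom_Acin2", "Moraxellaceae", "Acinetobacter"),
    ],
    "Pseudomonas": [
        ("OTU_dom_Pseu1", "Pseudomonadaceae", "Pseudomonas"),
        ("OTU_dom_Pseu2", "Pseudomonadaceae", "Pseudomonas"),
    ],
}
#: Split of a dominant genus' abundance over its two OTUs.
_DOMINANT_SPLIT = (0.6, 0.4)

_FAMILIES = (
    "Rhodobacteraceae",
    "SAR11_Clade_I",
    "Flavobacteriaceae",
    "Nitrosopumilaceae",
    "Saprospiraceae",
    "Pseudoalteromonadaceae",
    "SAR86_clade",
    "SAR324_clade",
    "Halieaceae",
    "Porticoccaceae",
    "Puniceicoccaceae",
    "Cryomorphaceae",
    "SAR116_clade",
    "Sphingomonadaceae",
    "Alteromonadaceae",
    "Vibrionaceae",
    "Colwelliaceae",
    "Marinimicrobia",
    "Thioglobaceae",
    "Nitrospinaceae",
    "Rubritaleaceae",
)


# ---------------------------------------------------------------------------
# scenario types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityCell:
    """Community structure of one (fraction, depth) cell.

    ``dominance`` lists (genus, target relative abundance) for designated
    dominant genera (two OTUs each); ``rank_abundance_shape`` is the geometric
    decay theta of the non-dominant series (``None`` = solved heuristically
    from the richness target); ``shared_fraction`` is the target pooled
    Jaccard overlap between the fast- and non-sinking pools at this depth.
    """

    target_richness: int
    dominance: tuple[tuple[str, float], ...] = ()
    rank_abundance_shape: float | None = None
    shared_fraction: float = 0.5
    library_size: int = DEFAULT_LIBRARY_SIZE
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        dom_mass = sum(a for _, a in self.dominance)
        if dom_mass >= 1:
            raise ValueError("dominance abundances must sum to < 1")
        if any(a <= 0 for _, a in self.dominance):
            raise ValueError("dominance abundances must be > 0")
        n_dom = sum(len(DOMINANT_OTUS.get(g, [(g,)])) for g, _ in self.dominance)
        if self.target_richness < max(1, n_dom):
            raise ValueError("target richness must cover the dominant OTUs")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.rank_abundance_shape is not None and not 0 < self.rank_abundance_shape < 1:
            raise ValueError("rank_abundance_shape must be in (0, 1)")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    @property
    def dominant_mass(self) -> float:
        return sum(a for _, a in self.dominance)

    def dominant_otus(self) -> list[tuple[str, float]]:
        """(otu_id, relative abundance) pairs for the dominant genera."""
        out: list[tuple[str, float]] = []
        for genus, mass in self.dominance:
            members = DOMINANT_OTUS.get(genus)
            if members is None:
                raise ValueError(f"no reserved OTUs for dominant genus {genus!r}")
            for (otu_id_, _, _), split in zip(members, _DOMINANT_SPLIT):
                out.append((otu_id_, mass * split))
        return out


@dataclass(frozen=True)
class CommunityScenario:
    """Community cells for the 'fast' and 'nonsink' fractions at each depth.

    Niskin samples are drawn from the non-sinking community (bottle water and
    MSC-top water are statistically indistinguishable in this design).
    """

    cells: dict[tuple[str, int], CommunityCell]
    depths_m: tuple[int, ...] = DEPTHS_M
    fractions: tuple[str, ...] = FRACTIONS
    n_replicates: int = N_REPLICATES
    global_pool_size: int = GLOBAL_POOL_SIZE

    def __post_init__(self) -> None:
        for depth in self.depths_m:
            for frac in ("fast", "nonsink"):
                if (frac, depth) not in self.cells:
                    raise ValueError(f"scenario missing cell for ({frac!r}, {depth})")

    def community_for(self, fraction: str, depth: int) -> CommunityCell:
        key = "fast" if fraction == "fast" else "nonsink"
        return self.cells[(key, depth)]


@dataclass(frozen=True)
class RateCell:
    """Rate parameters for one (fraction, depth) cell.

    ``mean_leucine_pmol_l_h`` is the volumetric uptake on the
    post-deconvolution (per litre of MSC-sampled seawater) scale for the
    fast-sinking fraction.  ``mean_cells_per_ml`` is on the same reference
    volume so that per-cell rates are the simple quotient.
    """

    mean_leucine_pmol_l_h: float
    mean_cells_per_ml: float
    sd_cells_per_ml: float = 0.0
    cv_replicates: float = 0.15

    def __post_init__(self) -> None:
        if self.mean_leucine_pmol_l_h <= 0 or self.mean_cells_per_ml <= 0:
            raise ValueError("rate means must be > 0")
        if self.cv_replicates < 0 or self.sd_cells_per_ml < 0:
            raise ValueError("cv and sd must be >= 0")


@dataclass(frozen=True)
class RateScenario:
    cells: dict[tuple[str, int], RateCell]
    incubation_h: dict[int, float] = field(
        default_factory=lambda: {28: 4.0, 70: 4.0, 128: 4.0, 500: 6.0}
    )
    depths_m: tuple[int, ...] = DEPTHS_M
    fractions: tuple[str, ...] = FRACTIONS
    n_replicates: int = N_REPLICATES

    def __post_init__(self) -> None:
        for frac in self.fractions:
            for depth in self.depths_m:
                if (frac, depth) not in self.cells:
                    raise ValueError(f"rate scenario missing cell ({frac!r}, {depth})")


@dataclass
class SyntheticDataset:
    """A complete simulated study from a seeded scenario."""

    otu_table: OtuTable
    taxonomy: pd.DataFrame
    rates: pd.DataFrame  # volumetric per-litre leucine replicates
    measurements: pd.DataFrame  # raw plate/top scale, with dilutions
    cells: pd.DataFrame
    geometry: MscGeometry
    seed: int
    community_scenario: CommunityScenario
    rate_scenario: RateScenario


def sample_id(fraction: str, depth_m: int, replicate: int) -> str:
    return f"{fraction}_{depth_m}m_r{replicate}"


# ---------------------------------------------------------------------------
# default study scenario
# ---------------------------------------------------------------------------

#: Richness anchors; interior depths are geometric interpolations.
_FAST_RICHNESS = {28: 314, 70: 262, 128: 200, 500: 128}
_NONSINK_RICHNESS = {28: 262, 70: 331, 128: 419, 500: 531}
#: Pooled-Jaccard overlap targets, log-interpolated between 0.53 and 0.16.
_SHARED = {28: 0.53, 70: 0.36, 128: 0.24, 500: 0.16}
_FAST_DOMINANCE: dict[int, tuple[tuple[str, float], ...]] = {
    28: (),
    70: (("Acinetobacter", 0.11),),
    128: (("Acinetobacter", 0.41), ("Pseudomonas", 0.16)),
    500: (("Acinetobacter", 0.75), ("Pseudomonas", 0.17)),
}

#: Volumetric PHP anchors (ng C L-1 h-1) give leucine means via the 1.55
#: ng C / pmol conversion; interior depths geometric.
_NONSINK_PHP = {28: 111.755, 70: 24.363, 128: 5.311, 500: 1.161}
_FAST_PHP = {28: 0.211, 70: 0.0511, 128: 0.01238, 500: 0.003}
_NONSINK_CELLS_ML = {28: 2.10e6, 70: 9.55e5, 128: 4.34e5, 500: 1.97e5}
#: Fast-sinking attached cells per mL of MSC-sampled seawater, set so that
#: cell-specific rates land at ~1.3e-7 ng C cell-1 h-1 at the profile ends
#: with a 4e-7 maximum at 128 m.
_FAST_CS = {28: 1.29e-7, 70: 1.4e-7, 128: 4.00e-7, 500: 1.53e-7}
_LEU_TO_C = 1.55
_CELL_CV = 0.45  # relative sd of cell concentrations


def default_scenario() -> tuple[CommunityScenario, RateScenario]:
    """The default study design: 3 fractions x 4 depths x 3 replicates."""
    cells: dict[tuple[str, int], CommunityCell] = {}
    for depth in DEPTHS_M:
        cells[("fast", depth)] = CommunityCell(
            target_richness=_FAST_RICHNESS[depth],
            dominance=_FAST_DOMINANCE[depth],
            shared_fraction=_SHARED[depth],
        )
        cells[("nonsink", depth)] = CommunityCell(
            target_richness=_NONSINK_RICHNESS[depth],
            shared_fraction=_SHARED[depth],
        )
    community = CommunityScenario(cells=cells)

    rate_cells: dict[tuple[str, int], RateCell] = {}
    for depth in DEPTHS_M:
        nonsink = RateCell(
            mean_leucine_pmol_l_h=_NONSINK_PHP[depth] / _LEU_TO_C,
            mean_cells_per_ml=_NONSINK_CELLS_ML[depth],
            sd_cells_per_ml=_CELL_CV * _NONSINK_CELLS_ML[depth],
        )
        rate_cells[("nonsink", depth)] = nonsink
        rate_cells[("niskin", depth)] = nonsink
        fast_cells_ml = _FAST_PHP[depth] / _FAST_CS[depth] / 1e3
        rate_cells[("fast", depth)] = RateCell(
            mean_leucine_pmol_l_h=_FAST_PHP[depth] / _LEU_TO_C,
            mean_cells_per_ml=fast_cells_ml,
            sd_cells_per_ml=_CELL_CV * fast_cells_ml,
        )
    rates = RateScenario(cells=rate_cells)
    return community, rates


# ---------------------------------------------------------------------------
# calibration machinery
# ---------------------------------------------------------------------------


def _default_shape(target_nondom: int, effective_library: float) -> float:
    """Heuristic geometric decay giving a detection saturation above target."""
    ratio = max(effective_library / max(target_nondom, 1), 3.0)
    theta = np.log(ratio) / max(target_nondom, 1)
    return float(np.clip(theta, 1e-4, 0.5))


def _geometric_props(n: int, theta: float, total_mass: float) -> np.ndarray:
    raw = (1.0 - theta) ** np.arange(n)
    return total_mass * raw / raw.sum()


def _expected_detected(props: np.ndarray, library: int) -> float:
    """Expected detected OTUs in a multinomial sample of the library size.

    The marginal count of OTU i is Binomial(library, p_i), so the expected
    number of OTUs with count > 0 is sum 1 - (1 - p_i)^library.
    """
    with np.errstate(over="ignore"):
        miss = np.exp(library * np.log1p(-np.minimum(props, 1 - 1e-15)))
    return float((1.0 - miss).sum())


@lru_cache(maxsize=256)
def _solve_truncation(
    target_nondom: int, theta: float, library: int, dom_mass: float
) -> int:
    """Smallest pool size whose expected detected richness hits the target."""
    if target_nondom < 1:
        return 0
    mass = 1.0 - dom_mass

    def expected(n: int) -> float:
        return _expected_detected(_geometric_props(n, theta, mass), library)

    lo = target_nondom
    hi = lo
    cap = max(60 * target_nondom, 600)
    while expected(hi) < target_nondom:
        hi *= 2
        if hi > cap:
            raise ValueError(
                "rank-abundance shape too steep: richness target "
                f"{target_nondom} not reachable at library size {library}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected(mid) < target_nondom:
            lo = mid
        else:
            hi = mid
    # pick the closer of the two bracketing sizes
    return hi if abs(expected(hi) - target_nondom) <= abs(expected(lo) - target_nondom) else lo


@dataclass(frozen=True)
class _CellComposition:
    """Solved abundance structure of one community cell."""

    nondom_props: np.ndarray
    dominant: tuple[tuple[str, float], ...]
    library: int
    n_replicates: int

    @property
    def pool_size(self) -> int:
        return len(self.nondom_props)

    def detection(self) -> np.ndarray:
        """Pooled (over replicates) detection probability per non-dominant rank."""
        with np.errstate(over="ignore"):
            miss = np.exp(self.library * np.log1p(-np.minimum(self.nondom_props, 1 - 1e-15)))
        return 1.0 - miss**self.n_replicates

    def expected_pooled_richness(self) -> float:
        dom = sum(
            1.0 - (1.0 - min(a, 1 - 1e-15)) ** (self.library * self.n_replicates)
            for _, a in self.dominant
        )
        return float(self.detection().sum()) + dom


def _compose_cell(cell: CommunityCell, n_replicates: int) -> _CellComposition:
    dominant = tuple(cell.dominant_otus())
    dom_mass = sum(a for _, a in dominant)
    target_nondom = cell.target_richness - len(dominant)
    theta = cell.rank_abundance_shape
    if theta is None:
        theta = _default_shape(target_nondom, cell.library_size * (1.0 - dom_mass))
    n = _solve_truncation(target_nondom, theta, cell.library_size, dom_mass)
    props = _geometric_props(n, theta, 1.0 - dom_mass) if n else np.empty(0)
    return _CellComposition(
        nondom_props=props,
        dominant=dominant,
        library=cell.library_size,
        n_replicates=n_replicates,
    )


def _shared_pool_size(
    fast: _CellComposition, nonsink: _CellComposition, jaccard: float
) -> int:
    """Number of shared identities giving the target expected observed Jaccard.

    Shared OTUs occupy random abundance ranks in each fraction, so the
    expected observed intersection is m * abar_f * abar_n with abar the mean
    pooled detection over non-dominant ranks; solving
    J = I / (E_f + E_n - I) for the intersection I gives m.
    """
    if jaccard <= 0:
        return 0
    det_f = fast.detection()
    det_n = nonsink.detection()
    if det_f.size == 0 or det_n.size == 0:
        return 0
    abar_f = float(det_f.mean())
    abar_n = float(det_n.mean())
    e_tot = fast.expected_pooled_richness() + nonsink.expected_pooled_richness()
    m = jaccard * e_tot / ((1.0 + jaccard) * abar_f * abar_n)
    return int(np.clip(round(m), 0, min(fast.pool_size, nonsink.pool_size)))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _taxonomy_for(otu_id_: str) -> tuple[str, str]:
    for members in DOMINANT_OTUS.values():
        for oid, fam, genus in members:
            if oid == otu_id_:
                return fam, genus
    idx = int(otu_id_.rsplit("_", 1)[-1])
    if idx % 10 < 3:  # roughly a third of OTUs lack a family-level assignment
        return "Unassigned", "Unassigned"
    fam = _FAMILIES[idx % len(_FAMILIES)]
    return fam, f"{fam}_genus{idx % 3 + 1}"


def generate_otu_table(
    scenario: CommunityScenario, seed: int | np.random.Generator = 0
) -> tuple[OtuTable, pd.DataFrame]:
    """Generate a seeded OTU count table and its taxonomy map.

    Identical seeds give identical tables.  Per depth, the fast and
    non-sinking identity pools are drawn from a common regional pool and
    partitioned into shared and private sets sized by the calibrated shared
    pool; abundance ranks are assigned by random permutation within each
    fraction.  Counts are multinomial draws at the cell's library size
    (Dirichlet-perturbed proportions when ``overdispersion`` > 0).
    """
    rng = np.random.default_rng(seed)
    width = len(str(scenario.global_pool_size))
    global_ids = np.array(
        [f"OTU_{i:0{width}d}" for i in range(1, scenario.global_pool_size + 1)]
    )

    compositions: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    for depth in scenario.depths_m:
        cell_f = scenario.cells[("fast", depth)]
        cell_n = scenario.cells[("nonsink", depth)]
        comp_f = _compose_cell(cell_f, scenario.n_replicates)
        comp_n = _compose_cell(cell_n, scenario.n_replicates)
        m = _shared_pool_size(comp_f, comp_n, cell_f.shared_fraction)
        union = comp_f.pool_size + comp_n.pool_size - m
        if union > scenario.global_pool_size:
            raise ValueError("global pool too small for the per-depth OTU pools")
        drawn = rng.choice(global_ids, size=union, replace=False)
        shared = drawn[:m]
        fast_priv = drawn[m : comp_f.pool_size]
        non_priv = drawn[comp_f.pool_size :]
        for frac, comp, ids in (
            ("fast", comp_f, np.concatenate([shared, fast_priv])),
            ("nonsink", comp_n, np.concatenate([shared, non_priv])),
        ):
            ranked = rng.permutation(ids)
            dom_ids = np.array([oid for oid, _ in comp.dominant], dtype=object)
            dom_props = np.array([a for _, a in comp.dominant], dtype=float)
            all_ids = np.concatenate([dom_ids, ranked]) if dom_ids.size else ranked
            all_props = (
                np.concatenate([dom_props, comp.nondom_props])
                if dom_ids.size
                else comp.nondom_props
            )
            compositions[(frac, depth)] = (all_ids, all_props)

    records: dict[str, dict[str, int]] = {}
    meta_rows = []
    for fraction in scenario.fractions:
        for depth in scenario.depths_m:
            key = "fast" if fraction == "fast" else "nonsink"
            ids, props = compositions[(key, depth)]
            cell = scenario.community_for(fraction, depth)
            for rep in range(1, scenario.n_replicates + 1):
                p = props
                if cell.overdispersion > 0:
                    alpha = np.maximum(props / cell.overdispersion, 1e-8)
                    p = rng.dirichlet(alpha)
                counts = rng.multinomial(cell.library_size, p / p.sum())
                sid = sample_id(fraction, depth, rep)
                nz = counts > 0
                records[sid] = dict(zip(ids[nz], counts[nz].astype(int)))
                meta_rows.append(
                    {"sample_id": sid, "fraction": fraction, "depth_m": depth, "replicate": rep}
                )

    counts_df = (
        pd.DataFrame.from_dict(records, orient="index")
        .fillna(0)
        .astype(np.int64)
        .sort_index(axis=1)
    )
    counts_df = counts_df.loc[[r["sample_id"] for r in meta_rows]]
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = OtuTable(counts_df, metadata)

    taxonomy = pd.DataFrame(
        [(_taxonomy_for(o)) for o in counts_df.columns],
        index=pd.Index(counts_df.columns, name="OTU_ID"),
        columns=["family", "genus"],
    )
    return table, taxonomy


def generate_rates(
    scenario: RateScenario, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded triplicate leucine uptakes and cell concentrations per sample.

    Replicate uptakes are lognormal around the cell mean with the stated CV
    (mean-preserving parameterisation; CV = 0 returns the mean exactly).
    Cell concentrations are truncated-normal (> 0).  Returns a long rates
    table (one row per replicate measurement, volumetric per-litre scale) and
    a per-sample cell table.
    """
    rng = np.random.default_rng(seed)
    rate_rows = []
    cell_rows = []
    for fraction in scenario.fractions:
        for depth in scenario.depths_m:
            cell = scenario.cells[(fraction, depth)]
            incubation = scenario.incubation_h.get(depth, 4.0)
            for rep in range(1, scenario.n_replicates + 1):
                sid = sample_id(fraction, depth, rep)
                mean = cell.mean_leucine_pmol_l_h
                cv = cell.cv_replicates
                if cv > 0:
                    sigma2 = np.log1p(cv**2)
                    mu = np.log(mean) - sigma2 / 2.0
                    draws = rng.lognormal(mu, np.sqrt(sigma2), size=3)
                else:
                    draws = np.full(3, mean)
                for k, value in enumerate(draws, start=1):
                    rate_rows.append(
                        {
                            "sample_id": sid,
                            "fraction": fraction,
                            "depth_m": depth,
                            "replicate": rep,
                            "rep": k,
                            "leu_pmol_l_h": float(value),
                            "incubation_h": incubation,
                        }
                    )
                if cell.sd_cells_per_ml > 0:
                    a = -cell.mean_cells_per_ml / cell.sd_cells_per_ml
                    conc = float(
                        stats.truncnorm.rvs(
                            a,
                            np.inf,
                            loc=cell.mean_cells_per_ml,
                            scale=cell.sd_cells_per_ml,
                            random_state=rng,
                        )
                    )
                else:
                    conc = cell.mean_cells_per_ml
                cell_rows.append(
                    {
                        "sample_id": sid,
                        "fraction": fraction,
                        "depth_m": depth,
                        "replicate": rep,
                        "cells_per_ml": conc,
                        "sd_cells_per_ml": cell.sd_cells_per_ml,
                    }
                )
    return pd.DataFrame(rate_rows), pd.DataFrame(cell_rows)


def plate_measurements(
    rates: pd.DataFrame,
    geometry: MscGeometry = MscGeometry(),
    fast_dilution: float = 2.0,
) -> pd.DataFrame:
    """Re-express volumetric rates as raw field measurements.

    Fast-sinking rows are converted back to the concentrated plate scale —
    the plate slurry carries the fast-sinking signal scaled by
    v_total / v_plate *plus* the ambient (non-sinking top) signal — and then
    diluted by ``fast_dilution`` to mimic slurry handling.  Niskin and
    MSC-top rows pass through with their sampler tags.  Deconvolving these
    measurements recovers the volumetric table exactly.
    """
    tag_map = {"niskin": "niskin", "nonsink": "nonsink_top"}
    ambient = rates[rates["fraction"] == "nonsink"].set_index(
        ["depth_m", "replicate", "rep"]
    )["leu_pmol_l_h"]
    rows = []
    for _, row in rates.iterrows():
        if row["fraction"] == "fast":
            amb = float(ambient.loc[(row["depth_m"], row["replicate"], row["rep"])])
            plate_true = (
                row["leu_pmol_l_h"] * geometry.v_total / geometry.v_plate + amb
            )
            value = plate_true / fast_dilution
            tag, dilution = "fast_plate", fast_dilution
        else:
            value, tag, dilution = row["leu_pmol_l_h"], tag_map[row["fraction"]], 1.0
        rows.append(
            {
                "sample_id": row["sample_id"],
                "fraction": row["fraction"],
                "depth_m": row["depth_m"],
                "replicate": row["replicate"],
                "rep": row["rep"],
                "msc_tag": tag,
                "value": float(value),
                "units": "pmol Leu L-1 h-1",
                "dilution": dilution,
                "incubation_h": row["incubation_h"],
            }
        )
    return pd.DataFrame(rows)


def generate_reference_profile(
    a: float,
    b: float,
    depths_m,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """(depth, concentration) pairs on the power law c = a * z**b.

    Noise, off by default, is multiplicative lognormal with the given sigma
    on the log scale.  Used as the reference sinking-pool profile for the
    ratio-transfer estimate of attached cells.
    """
    z = np.asarray(depths_m, dtype=float)
    if a <= 0:
        raise ValueError("scale a must be > 0")
    if np.any(z <= 0):
        raise ValueError("depths must be > 0")
    c = a * z**b
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c * np.exp(rng.normal(0.0, noise_sd, size=z.shape))
    return np.column_stack([z, c])


def simulate_dataset(
    community: CommunityScenario | None = None,
    rates: RateScenario | None = None,
    seed: int = 0,
    geometry: MscGeometry | None = None,
    fast_dilution: float = 2.0,
) -> SyntheticDataset:
    """Generate a complete seeded study (counts + taxonomy + rates + cells)."""
    if community is None or rates is None:
        default_c, default_r = default_scenario()
        community = community or default_c
        rates = rates or default_r
    geometry = geometry or MscGeometry()
    ss = np.random.SeedSequence(seed)
    table_rng, rate_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    table, taxonomy = generate_otu_table(community, table_rng)
    rate_df, cell_df = generate_rates(rates, rate_rng)
    measurements = plate_measurements(rate_df, geometry, fast_dilution)
    return SyntheticDataset(
        otu_table=table,
        taxonomy=taxonomy,
        rates=rate_df,
        measurements=measurements,
        cells=cell_df,
        geometry=geometry,
        seed=seed,
        community_scenario=community,
        rate_scenario=rates,
    )


# ---------------------------------------------------------------------------
# calibration summaries (used by the tests and the acceptance script)
# ---------------------------------------------------------------------------


def calibration_summary(
    scenario: CommunityScenario | None = None,
    n_datasets: int = 50,
    seed: int = 1,
) -> dict[str, pd.DataFrame]:
    """Monte-Carlo calibration of the community generator.

    Generates ``n_datasets`` seeded tables and returns mean observed richness
    per (fraction, depth), the mean shared-OTU percentage between the pooled
    fast and non-sinking fractions per depth, and the mean summed relative
    abundance of the dominant genera in fast-sinking samples per depth.
    """
    if scenario is None:
        scenario, _ = default_scenario()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_datasets)
    rich_acc: dict[tuple[str, int], list[float]] = {}
    shared_acc: dict[int, list[float]] = {d: [] for d in scenario.depths_m}
    dom_acc: dict[int, list[float]] = {d: [] for d in scenario.depths_m}
    dom_ids = [oid for members in DOMINANT_OTUS.values() for oid, _, _ in members]
    for s in seeds:
        table, _ = generate_otu_table(scenario, int(s))
        rich = observed_richness(table)
        meta = table.metadata
        for (frac, depth), group in meta.groupby(["fraction", "depth_m"]):
            rich_acc.setdefault((frac, int(depth)), []).append(
                float(rich.loc[group.index].mean())
            )
        for depth in scenario.depths_m:
            fast_ids = meta.index[(meta["fraction"] == "fast") & (meta["depth_m"] == depth)]
            non_ids = meta.index[
                (meta["fraction"] == "nonsink") & (meta["depth_m"] == depth)
            ]
            shared_acc[depth].append(shared_otus(table, fast_ids, non_ids))
            present = [c for c in dom_ids if c in table.counts.columns]
            sub = table.counts.loc[fast_ids]
            dom_share = (
                sub[present].sum(axis=1) / sub.sum(axis=1) if present else 0.0
            )
            dom_acc[depth].append(float(np.mean(dom_share)))
    richness = pd.DataFrame(
        [
            {
                "fraction": frac,
                "depth_m": depth,
                "mean_observed": float(np.mean(vals)),
                "target": scenario.community_for(frac, depth).target_richness,
            }
            for (frac, depth), vals in sorted(rich_acc.items())
        ]
    )
    shared = pd.DataFrame(
        [
            {
                "depth_m": d,
                "mean_shared_pct": float(np.mean(v)),
                "target_pct": 100.0 * scenario.cells[("fast", d)].shared_fraction,
            }
            for d, v in shared_acc.items()
        ]
    )
    dominance = pd.DataFrame(
        [
            {
                "depth_m": d,
                "mean_dominant_share": float(np.mean(v)),
                "target": scenario.cells[("fast", d)].dominant_mass,
            }
            for d, v in dom_acc.items()
        ]
    )
    return {"richness": richness, "shared": shared, "dominance": dominance}
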