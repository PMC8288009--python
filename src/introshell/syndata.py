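"""Synthetic Mytilus cohorts for testing the introgression pipeline.

Generates everything the downstream analyses consume, at desk scale and with
known ground truth: genotypes at a panel of taxon-diagnostic biallelic SNPs,
Me15/16 fragment calls, shell measurements (length, height, wet weights,
puncture force), closed valve outlines, and per-depth salinity series.

The generative model mirrors a rope-cultivated stock of the *Mytilus edulis*
species complex (ME = *M. edulis*, MG = *M. galloprovincialis*,
MT = *M. trossulus*) sampled at nominal depths of 1, 3, 5 and 7 m:

* Genotypes follow a Mendelian gamete-pool law.  Each individual draws two
  alleles per locus from the gamete pools of its two parents.  Pure classes
  draw both alleles from one species' allele frequencies; F1 hybrids draw one
  from each parental species; first backcrosses draw one F1 gamete (a coin
  flip between the two grandparental pools at every locus) and one pure
  gamete.
* A locus is "strictly diagnostic" when the MT allele is fixed in MT and
  absent in ME and MG.  Leaky loci carry the nominally diagnostic allele at a
  low frequency in ME/MG, emulating the detection floor of a small SNP
  discovery panel.
* Normalised shell strength (kg per cm of shell length) is linear in depth
  and in the individual's realised MT allele frequency, with Gaussian noise.
* The shell length:height ratio (elongation) increases with MT ancestry and
  decreases with depth; valve outlines are an anisotropically scaled
  mussel-like template whose bounding-box ratio equals the requested
  elongation exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "LocusSpec",
    "PanelSpec",
    "CohortDesign",
    "Cohort",
    "ShellTraitParams",
    "ANCESTRY_CLASSES",
    "simulate_panel",
    "simulate_cohort",
    "inject_missingness",
    "simulate_me1516",
    "simulate_shell_traits",
    "draw_mt_af_from_bins",
    "simulate_outline",
    "rasterize",
    "simulate_salinity",
    "default_panel",
    "default_design",
]

# Fragment sizes (bp) of the Me15/16 adhesive-protein marker per species.
ME1516_FRAGMENT = {"ME": 180, "MT": 168, "MG": 126}

# Ancestry classes: pure species, first-generation hybrids, first backcrosses.
# Each class is described by its two parental gamete sources; a source is a
# species code or a tuple (A, B) denoting an F1(A×B) parent.
_PARENTS: dict[str, tuple] = {
    "PURE_ME": ("ME", "ME"),
    "PURE_MG": ("MG", "MG"),
    "PURE_MT": ("MT", "MT"),
    "F1_ME_MG": ("ME", "MG"),
    "F1_ME_MT": ("ME", "MT"),
    "BC_ME_MT_TO_ME": (("ME", "MT"), "ME"),
    "BC_ME_MT_TO_MT": (("ME", "MT"), "MT"),
    "BC_ME_MG_TO_ME": (("ME", "MG"), "ME"),
}
ANCESTRY_CLASSES = tuple(_PARENTS)


@dataclass(frozen=True)
class LocusSpec:
    """One biallelic locus of the MT-diagnostic panel.

    ``diag_freq_MT`` is the frequency of the MT-diagnostic allele in pure MT;
    ``leak_freq_ME``/``leak_freq_MG`` its (ideally zero) frequency in the
    other two species.  The QC flags mark assay failure modes.
    """

    id: str
    diag_freq_MT: float = 1.0
    leak_freq_ME: float = 0.0
    leak_freq_MG: float = 0.0
    ambiguous_flag: bool = False
    cluster_fail_flag: bool = False
    false_call_flag: bool = False

    def __post_init__(self) -> None:
        for name in ("diag_freq_MT", "leak_freq_ME", "leak_freq_MG"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.diag_freq_MT < max(self.leak_freq_ME, self.leak_freq_MG):
            raise ValueError(
                f"locus {self.id}: diagnostic frequency in MT must be >= "
                "leak frequencies in ME/MG"
            )

    @property
    def strictly_diagnostic(self) -> bool:
        return (
            self.diag_freq_MT == 1.0
            and self.leak_freq_ME == 0.0
            and self.leak_freq_MG == 0.0
        )

    def freq(self, species: str) -> float:
        return {
            "MT": self.diag_freq_MT,
            "ME": self.leak_freq_ME,
            "MG": self.leak_freq_MG,
        }[species]


@dataclass(frozen=True)
class PanelSpec:
    loci: tuple[LocusSpec, ...]

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class CohortDesign:
    """Per-depth sample sizes and ancestry-class mixtures.

    ``mixture`` maps depth (m) to a mapping ancestry class -> proportion;
    proportions at each depth must sum to 1.
    """

    n_by_depth: dict[float, int]
    mixture: dict[float, dict[str, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        for d, n in self.n_by_depth.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"sample size at {d} m must be a positive integer")
            mix = self.mixture.get(d)
            if mix is None:
                raise ValueError(f"no ancestry mixture for depth {d} m")
            for cls in mix:
                if cls not in _PARENTS:
                    raise ValueError(f"unknown ancestry class {cls!r}")
            tot = sum(mix.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"mixture at {d} m sums to {tot}, expected 1")

    def scaled(self, factor: int) -> "CohortDesign":
        """Same mixtures with every per-depth count multiplied by ``factor``."""
        return replace(
            self, n_by_depth={d: int(n * factor) for d, n in self.n_by_depth.items()}
        )


@dataclass
class Cohort:
    """A simulated stock: genotype matrix plus per-individual metadata.

    ``genotypes``: individuals x loci, cells are the within-genotype frequency
    of the MT-diagnostic allele (0, 0.5 or 1) or NaN for missing calls.
    ``meta`` carries id, depth_m and the true ancestry label.
    """

    genotypes: pd.DataFrame
    meta: pd.DataFrame
    panel: PanelSpec

    @property
    def individual_ids(self) -> list[str]:
        return list(self.genotypes.index)

    def mt_allele_frequency(self) -> pd.Series:
        """Realised per-individual MT allele frequency over non-missing loci."""
        return self.genotypes.mean(axis=1, skipna=True)


# ---------------------------------------------------------------------------
# panel and genotypes


def simulate_panel(
    n_loci: int, n_strict: int, leak_freq: float, seed: int = 0
) -> PanelSpec:
    """Build a diagnostic panel with ``n_strict`` strictly diagnostic loci.

    The remaining loci carry the diagnostic allele at frequency ``leak_freq``
    in both ME and MG, emulating markers wrongly classified as fixed because
    the discovery sample was small.
    """
    if n_loci <= 0 or n_strict < 0 or n_strict > n_loci:
        raise ValueError(
            f"need 0 <= n_strict <= n_loci, got n_strict={n_strict}, n_loci={n_loci}"
        )
    if not (0.0 <= leak_freq < 0.5):
        raise ValueError(f"leak_freq must be in [0, 0.5), got {leak_freq}")
    width = max(2, len(str(n_loci)))
    loci = []
    for i in range(n_loci):
        leak = 0.0 if i < n_strict else leak_freq
        loci.append(
            LocusSpec(
                id=f"L{i + 1:0{width}d}",
                diag_freq_MT=1.0,
                leak_freq_ME=leak,
                leak_freq_MG=leak,
            )
        )
    return PanelSpec(loci=tuple(loci))


def _gamete(rng: np.random.Generator, source, freqs: np.ndarray) -> np.ndarray:
    """Draw one gamete (0/1 per locus) from a species or F1 source.

    ``freqs`` is a (3, n_loci) array of diagnostic-allele frequencies indexed
    by species code via ``_SP_IDX``.
    """
    if isinstance(source, tuple):  # F1 parent: coin flip between the two pools
        a = _gamete(rng, source[0], freqs)
        b = _gamete(rng, source[1], freqs)
        pick = rng.integers(0, 2, size=a.shape).astype(bool)
        return np.where(pick, a, b)
    f = freqs[_SP_IDX[source]]
    return (rng.random(f.shape) < f).astype(np.int8)


_SP_IDX = {"ME": 0, "MG": 1, "MT": 2}


def simulate_cohort(design: CohortDesign, panel: PanelSpec) -> Cohort:
    """Draw a cohort of genotypes under the Mendelian gamete-pool law."""
    freqs = np.array(
        [
            [l.freq("ME") for l in panel.loci],
            [l.freq("MG") for l in panel.loci],
            [l.freq("MT") for l in panel.loci],
        ]
    )
    rng = stream(design.seed, "cohort")
    rows, ids, depths, classes = [], [], [], []
    counter = 0
    for depth in sorted(design.n_by_depth):
        n = design.n_by_depth[depth]
        mix = design.mixture[depth]
        labels = list(mix)
        counts = _apportion(n, [mix[c] for c in labels])
        for cls, k in zip(labels, counts):
            p1, p2 = _PARENTS[cls]
            for _ in range(k):
                counter += 1
                g = (_gamete(rng, p1, freqs) + _gamete(rng, p2, freqs)) / 2.0
                rows.append(g)
                ids.append(f"ind{counter:05d}")
                depths.append(depth)
                classes.append(cls)
    genotypes = pd.DataFrame(
        np.asarray(rows, dtype=float), index=ids, columns=panel.locus_ids
    )
    meta = pd.DataFrame(
        {"individual_id": ids, "depth_m": depths, "ancestry": classes}
    ).set_index("individual_id", drop=False)
    return Cohort(genotypes=genotypes, meta=meta, panel=panel)


def _apportion(n: int, props: list[float]) -> list[int]:
    """Largest-remainder rounding of ``n * props`` to integers summing to n."""
    raw = np.asarray(props) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def inject_missingness(
    cohort: Cohort,
    locus_rates: float | dict[str, float] = 0.0,
    indiv_rates: float | dict[str, float] = 0.0,
    seed: int = 0,
) -> Cohort:
    """Flag calls as missing (NaN) at the requested per-locus/individual rates.

    A cell is dropped if either its locus draw or its individual draw fires,
    so with one dimension at rate 0 the other dimension's empirical missing
    fraction is an unbiased estimate of its requested rate.
    """
    g = cohort.genotypes.copy()
    lr = _as_rate_vector(locus_rates, g.columns, "locus")
    ir = _as_rate_vector(indiv_rates, g.index, "individual")
    rng = stream(seed, "missingness")
    p_cell = 1.0 - np.outer(1.0 - ir, 1.0 - lr)
    mask = rng.random(g.shape) < p_cell
    g.values[mask] = np.nan
    return Cohort(genotypes=g, meta=cohort.meta.copy(), panel=cohort.panel)


def _as_rate_vector(rates, index, what: str) -> np.ndarray:
    if isinstance(rates, dict):
        vec = np.array([float(rates.get(k, 0.0)) for k in index])
    else:
        vec = np.full(len(index), float(rates))
    if ((vec < 0) | (vec > 1)).any():
        raise ValueError(f"{what} missingness rates must be in [0, 1]")
    return vec


# ---------------------------------------------------------------------------
# Me15/16 marker


def simulate_me1516(cohort: Cohort, seed: int = 0) -> pd.DataFrame:
    """Fragment presence at the Me15/16 locus per individual.

    Pure classes show the single species-specific fragment (ME 180 bp,
    MT 168 bp, MG 126 bp); F1 hybrids show both parental fragments; a
    backcross segregates: its F1-derived allele is a coin flip between the
    two grandparental species.

    Returns a DataFrame with columns individual_id, fragments (frozenset of
    fragment sizes in bp).
    """
    rng = stream(seed, "me1516")
    records = []
    for ind, cls in zip(cohort.meta["individual_id"], cohort.meta["ancestry"]):
        if cls not in _PARENTS:
            raise ValueError(f"unknown ancestry label {cls!r} for {ind}")
        alleles = []
        for parent in _PARENTS[cls]:
            if isinstance(parent, tuple):
                alleles.append(parent[rng.integers(0, 2)])
            else:
                alleles.append(parent)
        frags = frozenset(ME1516_FRAGMENT[sp] for sp in alleles)
        records.append({"individual_id": ind, "fragments": frags})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# shell traits


@dataclass(frozen=True)
class ShellTraitParams:
    """Generative parameters for shell measurements.

    Strength is on the length-normalised scale (kg cm^-1 SL):
    ``baseline_strength_at_1m + depth_slope*(depth-1) + mt_effect*MT_AF``
    plus Gaussian noise.  Elongation (SL:SH) is linear in MT_AF and depth.
    Defaults place a non-introgressed 1 m mussel at 2.03 kg cm^-1 SL, with
    strength rising 0.135 per metre of depth and falling 1.37 per unit MT
    allele frequency.
    """

    baseline_strength_at_1m: float = 2.03
    depth_slope: float = 0.135
    mt_effect: float = -1.37
    residual_sd: float = 0.65
    length_mean: float = 55.0
    length_sd: float = 6.0
    ratio_base: float = 1.95
    ratio_mt_effect: float = 0.40
    ratio_depth_slope: float = -0.02
    ratio_sd: float = 0.08

    def __post_init__(self) -> None:
        vals = [getattr(self, f.name) for f in self.__dataclass_fields__.values()]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("shell-trait parameters must be finite")
        if self.residual_sd < 0 or self.ratio_sd < 0 or self.length_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_shell_traits(
    cohort: Cohort, params: ShellTraitParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate shell records (SL, SH, wet weights, puncture force) per individual.

    The raw puncture force is back-computed from the normalised strength and
    the generated shell length, so re-normalising force by length recovers the
    linear model exactly (up to the injected noise).
    """
    params = params or ShellTraitParams()
    rng = stream(seed, "shell")
    meta = cohort.meta
    n = len(meta)
    mt_af = cohort.mt_allele_frequency().reindex(meta.index).to_numpy()
    depth = meta["depth_m"].to_numpy(dtype=float)

    strength = (
        params.baseline_strength_at_1m
        + params.depth_slope * (depth - 1.0)
        + params.mt_effect * mt_af
        + rng.normal(0.0, params.residual_sd, n)
    )
    strength = np.clip(strength, 0.05, None)  # a punctured shell resists > 0

    sl = np.clip(rng.normal(params.length_mean, params.length_sd, n), 20.0, None)
    ratio = (
        params.ratio_base
        + params.ratio_mt_effect * mt_af
        + params.ratio_depth_slope * (depth - 1.0)
        + rng.normal(0.0, params.ratio_sd, n)
    )
    ratio = np.clip(ratio, 1.05, None)
    sh = sl / ratio

    # allometric wet weights with mild lognormal scatter; these exist so the
    # collinearity screen has realistically correlated predictors to find
    tww = 1.2e-4 * sl**2.9 * rng.lognormal(0.0, 0.08, n)
    wws = 0.45 * tww * rng.lognormal(0.0, 0.05, n)

    force = strength * (sl / 10.0)  # kg; SL converted mm -> cm
    return pd.DataFrame(
        {
            "individual_id": meta["individual_id"].to_numpy(),
            "depth_m": depth,
            "mt_af": mt_af,
            "SL_mm": sl,
            "SH_mm": sh,
            "TWW_g": tww,
            "WWS_g": wws,
            "force_kg": force,
            "strength_norm": strength,
        }
    ).set_index("individual_id", drop=False)


def draw_mt_af_from_bins(
    bin_counts: dict[str, int],
    n_loci: int = 33,
    seed: int = 0,
) -> np.ndarray:
    """Draw MT allele frequencies matching observed introgression-bin counts.

    ``bin_counts`` maps {"NONE", "LT10", "10_50", "50_75", "GT75"} to counts.
    Zeros for the NONE class; within each positive bin, values are uniform on
    the bin's range (the LT10 lower edge is one allele copy, 1/(2*n_loci)).
    """
    rng = stream(seed, "mtaf_bins")
    lo_hi = {
        "LT10": (1.0 / (2 * n_loci), 0.10),
        "10_50": (0.10, 0.50),
        "50_75": (0.50, 0.75),
        "GT75": (0.75, 1.0),
    }
    out = [np.zeros(int(bin_counts.get("NONE", 0)))]
    for name, (lo, hi) in lo_hi.items():
        k = int(bin_counts.get(name, 0))
        out.append(rng.uniform(lo, hi, k))
    vals = np.concatenate(out)
    return vals[rng.permutation(len(vals))]


# ---------------------------------------------------------------------------
# outlines


def _mussel_template(n_points: int) -> np.ndarray:
    """Closed mussel-like base outline (n_points x 2), counterclockwise.

    A smooth polar curve: egg-shaped with a drawn-out posterior margin and a
    flattened ventral line, loosely matching a lateral valve view.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = 1.0 + 0.32 * np.cos(t) + 0.10 * np.cos(2 * t) - 0.06 * np.sin(t)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def simulate_outline(
    elongation: float,
    n_points: int = 300,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic valve outline with an exact bounding-box length:height ratio.

    The template is scaled anisotropically so that its bounding box has
    width:height equal to ``elongation`` before smooth radial noise (relative
    amplitude ``noise_sd``) is applied.  Returns an (n_points, 2) array, closed
    implicitly (first point not repeated), counterclockwise.
    """
    if elongation <= 0:
        raise ValueError("elongation must be positive")
    if n_points < 32:
        raise ValueError(f"need at least 32 outline points, got {n_points}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    xy = _mussel_template(n_points)
    w = xy[:, 0].max() - xy[:, 0].min()
    h = xy[:, 1].max() - xy[:, 1].min()
    xy[:, 0] *= elongation * h / w
    if noise_sd > 0:
        rng = stream(seed, "outline")
        raw = rng.normal(0.0, 1.0, n_points)
        kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(np.tile(raw, 3), kernel, mode="same")[
            n_points : 2 * n_points
        ]
        c = xy.mean(axis=0)
        rad = xy - c
        scale = np.hypot(rad[:, 0], rad[:, 1]).mean()
        unit = rad / np.hypot(rad[:, 0], rad[:, 1])[:, None]
        xy = xy + unit * (noise_sd * scale * smooth)[:, None]
    return xy


def rasterize(outline: np.ndarray, px_per_unit: float = 50.0) -> np.ndarray:
    """Binary mask of the filled outline (row 0 at the bottom, y upward)."""
    from skimage.draw import polygon

    xy = np.asarray(outline, dtype=float) * px_per_unit
    pad = 3
    xy = xy - xy.min(axis=0) + pad
    shape = tuple(np.ceil(xy.max(axis=0)).astype(int)[::-1] + pad)
    img = np.zeros(shape, dtype=bool)
    rr, cc = polygon(xy[:, 1], xy[:, 0], shape=shape)
    img[rr, cc] = True
    return img


# ---------------------------------------------------------------------------
# salinity


def simulate_salinity(
    depths: list[float],
    mean_by_depth: list[float],
    var_by_depth: list[float],
    n_steps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-depth salinity series (practical salinity, dimensionless).

    Emulates a stratified loch: configure shallow depths with lower means and
    higher variances.  Returns a tidy frame (depth_m, t, S).
    """
    if not (len(depths) == len(mean_by_depth) == len(var_by_depth)):
        raise ValueError("depths, means and variances must have equal length")
    if any(v < 0 for v in var_by_depth):
        raise ValueError("variances must be non-negative")
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = stream(seed, "salinity")
    frames = []
    for d, m, v in zip(depths, mean_by_depth, var_by_depth):
        s = np.clip(rng.normal(m, np.sqrt(v), n_steps), 0.0, None)
        frames.append(pd.DataFrame({"depth_m": d, "t": np.arange(n_steps), "S": s}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# study-scale defaults


def default_panel(seed: int = 0) -> PanelSpec:
    """33-locus panel: 28 strict plus 5 leaking at the 1.4% detection floor."""
    return simulate_panel(n_loci=33, n_strict=28, leak_freq=0.014, seed=seed)


def default_design(seed: int = 0) -> CohortDesign:
    """Study-scale cohort design: 435 mussels over 4 depths.

    Mixtures emulate the observed stock: dominated by pure ME with ME x MG
    hybrids, rare pure MT and ME x MT F1s concentrated at shallow depth, and
    a few MT backcrosses.  Class counts per depth are converted to
    proportions of the per-depth sample sizes (116, 118, 118, 83).
    """
    counts = {
        1.0: {"PURE_MT": 3, "BC_ME_MT_TO_MT": 2, "F1_ME_MT": 2, "F1_ME_MG": 11},
        3.0: {"PURE_MT": 2, "BC_ME_MT_TO_MT": 1, "F1_ME_MT": 4, "F1_ME_MG": 21},
        5.0: {"PURE_MT": 1, "BC_ME_MT_TO_MT": 2, "F1_ME_MT": 1, "F1_ME_MG": 18},
        7.0: {"PURE_MT": 0, "BC_ME_MT_TO_MT": 0, "F1_ME_MT": 1, "F1_ME_MG": 13},
    }
    n_by_depth = {1.0: 116, 3.0: 118, 5.0: 118, 7.0: 83}
    mixture = {}
    for d, n in n_by_depth.items():
        mix = {cls: k / n for cls, k in counts[d].items() if k > 0}
        mix["PURE_ME"] = 1.0 - sum(mix.values())
        mixture[d] = mix
    return CohortDesign(n_by_depth=n_by_depth, mixture=mixture, seed=seed)
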