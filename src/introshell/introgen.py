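"""Species classification and per-individual introgression statistics.

Two marker systems are handled:

* the single nuclear Me15/16 marker, whose PCR fragment sizes are species
  specific (ME 180 bp, MT 168 bp, MG 126 bp) — one fragment means a pure
  species, two a putative hybrid;
* a panel of MT-diagnostic SNPs scored as the within-genotype frequency of
  the diagnostic allele (0, 0.5, 1 or missing).

From the SNP panel three per-individual statistics are computed over the
M non-missing retained loci: observed heterozygosity H_O = nXY/M, hybrid
index HI = (nXY + nXX)/M, and the MT allele frequency
MT_AF = (nXY + 2 nXX)/(2M), where nXY and nXX count loci heterozygous and
homozygous for the diagnostic allele.  MT_AF = HI - H_O/2 identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

__all__ = [
    "Me1516Call",
    "IntrogressionProfile",
    "call_me1516",
    "tabulate_classes",
    "qc_filter",
    "introgression_profile",
    "profiles_frame",
    "summarize_introgression",
    "maf_detection_limit",
    "cluster_heatmap_order",
    "concordance_me1516_snp",
    "BIN_LABELS",
]

_FRAGMENT_SPECIES = {180: "ME", 168: "MT", 126: "MG"}
_CLASS_ORDER = ["ME", "MG", "MT", "ME×MG", "ME×MT", "MG×MT"]
BIN_LABELS = ("NONE", "LT10", "10_50", "50_75", "GT75")


@dataclass(frozen=True)
class Me1516Call:
    individual_id: str
    fragments: frozenset
    species_class: str


def call_me1516(fragments, individual_id: str = "") -> Me1516Call:
    """Classify an individual from its Me15/16 fragment sizes.

    One fragment -> pure species; two -> putative hybrid; zero or all three
    -> UNDETERMINED (logged, not an exception — mirrors failed PCRs).
    """
    frags = frozenset(int(f) for f in fragments)
    unknown = frags - set(_FRAGMENT_SPECIES)
    if unknown:
        raise ValueError(f"unknown Me15/16 fragment sizes: {sorted(unknown)}")
    species = sorted(
        (_FRAGMENT_SPECIES[f] for f in frags),
        key=["ME", "MG", "MT"].index,
    )
    if len(species) == 1:
        cls = species[0]
    elif len(species) == 2:
        cls = "×".join(species)
    else:
        cls = "UNDETERMINED"
        log.info(
            "individual %s: %d Me15/16 fragments -> UNDETERMINED",
            individual_id or "?",
            len(frags),
        )
    return Me1516Call(individual_id=individual_id, fragments=frags, species_class=cls)


def tabulate_classes(calls, depths) -> pd.DataFrame:
    """Per-depth genotype-class proportions and species allele frequencies.

    ``calls``: iterable of Me1516Call; ``depths``: mapping individual_id ->
    depth (or aligned sequence).  UNDETERMINED calls are excluded from all
    denominators.  The allele frequency of species k at a depth counts two
    alleles per pure individual and one per hybrid carrying k, over 2n.
    Includes a pooled row with depth label "all".
    """
    calls = list(calls)
    if isinstance(depths, (dict, pd.Series)):
        dvals = [depths[c.individual_id] for c in calls]
    else:
        dvals = list(depths)
        if len(dvals) != len(calls):
            raise ValueError("depths must align with calls")
    rows = {}
    for c, d in zip(calls, dvals):
        if c.species_class == "UNDETERMINED":
            continue
        rows.setdefault(d, []).append(c.species_class)

    def _summary(classes: list[str], label) -> dict:
        n = len(classes)
        if n == 0:
            raise ValueError(f"empty depth stratum {label!r}")
        out = {"depth": label, "n": n}
        for cls in _CLASS_ORDER:
            out[f"prop_{cls}"] = classes.count(cls) / n
        for sp in ("ME", "MG", "MT"):
            copies = sum(
                2 if cls == sp else (1 if sp in cls.split("×") else 0)
                for cls in classes
            )
            out[f"freq_{sp}"] = copies / (2 * n)
        return out

    recs = [_summary(rows[d], d) for d in sorted(rows)]
    recs.append(_summary([c for v in rows.values() for c in v], "all"))
    return pd.DataFrame(recs)


def qc_filter(
    matrix: pd.DataFrame,
    locus_flags: pd.DataFrame | None = None,
    missing_threshold: float = 0.2,
    individual_flags: pd.Series | None = None,
):
    """Panel and individual quality control.

    Loci are removed first — if any failure flag (``cluster_fail``,
    ``false_call``, ``ambiguous``) is set or the per-locus missing fraction
    exceeds ``missing_threshold`` — then individuals are removed if QC-flagged
    or missing at more than the threshold of the *retained* loci.

    Returns ``(filtered_matrix, report)`` where the report is a dict with
    ``loci`` and ``individuals`` DataFrames recording every exclusion and its
    reason, and the filter is idempotent on its own output.
    """
    if not (0.0 < missing_threshold <= 1.0):
        raise ValueError("missing_threshold must be in (0, 1]")
    flags = pd.DataFrame(
        False,
        index=matrix.columns,
        columns=["cluster_fail", "false_call", "ambiguous"],
    )
    if locus_flags is not None:
        for col in flags.columns:
            if col in locus_flags:
                flags[col] = (
                    locus_flags[col].reindex(matrix.columns).fillna(False).astype(bool)
                )

    loc_missing = matrix.isna().mean(axis=0)
    loc_rows = []
    for locus in matrix.columns:
        reasons = [c for c in flags.columns if flags.at[locus, c]]
        if loc_missing[locus] > missing_threshold:
            reasons.append("missing_gt_threshold")
        loc_rows.append(
            {
                "locus_id": locus,
                "missing_fraction": loc_missing[locus],
                "retained": not reasons,
                "reason": ";".join(reasons),
            }
        )
    loci_report = pd.DataFrame(loc_rows).set_index("locus_id")
    kept_loci = loci_report.index[loci_report["retained"]]
    if len(kept_loci) == 0:
        raise ValueError("empty panel: QC removed every locus")
    sub = matrix[kept_loci]

    qc_fail = pd.Series(False, index=matrix.index)
    if individual_flags is not None:
        qc_fail = individual_flags.reindex(matrix.index).fillna(False).astype(bool)
    ind_missing = sub.isna().mean(axis=1)
    ind_rows = []
    for ind in matrix.index:
        reasons = []
        if qc_fail[ind]:
            reasons.append("qc_fail")
        if ind_missing[ind] > missing_threshold:
            reasons.append("missing_gt_threshold")
        ind_rows.append(
            {
                "individual_id": ind,
                "missing_fraction": ind_missing[ind],
                "retained": not reasons,
                "reason": ";".join(reasons),
            }
        )
    ind_report = pd.DataFrame(ind_rows).set_index("individual_id")
    kept_ind = ind_report.index[ind_report["retained"]]
    report = {"loci": loci_report, "individuals": ind_report}
    out = sub.loc[kept_ind]
    out.index.name = matrix.index.name
    out.columns.name = matrix.columns.name
    return out, report


@dataclass(frozen=True)
class IntrogressionProfile:
    """Per-individual MT-introgression statistics over retained loci."""

    individual_id: str
    M: int
    nXY: int
    nXX: int
    H_O: float
    HI: float
    MT_AF: float
    bin: str
    f1_like: bool


def introgression_profile(row, individual_id: str = "") -> IntrogressionProfile:
    """Summarise one genotype row (dosages in {0, 0.5, 1} or NaN).

    Bins on MT_AF: NONE (no diagnostic allele), (0, 0.10) -> LT10,
    [0.10, 0.50) -> 10_50, [0.50, 0.75) -> 50_75, [0.75, 1] -> GT75.
    ``f1_like`` flags profiles consistent with a first-generation ME x MT
    hybrid: MT_AF in [0.35, 0.5] and at least 80% of MT-positive loci
    heterozygous.
    """
    if isinstance(row, pd.Series):
        individual_id = individual_id or str(row.name)
        vals = row.to_numpy(dtype=float)
    else:
        vals = np.asarray(row, dtype=float)
    ok = ~np.isnan(vals)
    m = int(ok.sum())
    if m == 0:
        raise ValueError(f"uninformative individual {individual_id!r}: all calls missing")
    bad = set(np.unique(vals[ok])) - {0.0, 0.5, 1.0}
    if bad:
        raise ValueError(f"invalid dosage values {sorted(bad)}")
    nxy = int((vals[ok] == 0.5).sum())
    nxx = int((vals[ok] == 1.0).sum())
    h_o = nxy / m
    hi = (nxy + nxx) / m
    mt_af = (nxy + 2 * nxx) / (2 * m)
    if nxy + nxx == 0:
        b = "NONE"
    elif mt_af < 0.10:
        b = "LT10"
    elif mt_af < 0.50:
        b = "10_50"
    elif mt_af < 0.75:
        b = "50_75"
    else:
        b = "GT75"
    f1 = (
        nxy + nxx > 0
        and 0.35 <= mt_af <= 0.5
        and nxy / (nxy + nxx) >= 0.8
    )
    return IntrogressionProfile(
        individual_id=individual_id,
        M=m,
        nXY=nxy,
        nXX=nxx,
        H_O=h_o,
        HI=hi,
        MT_AF=mt_af,
        bin=b,
        f1_like=f1,
    )


def profiles_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    """Introgression profiles for every row of a genotype matrix."""
    profs = [introgression_profile(matrix.loc[i], str(i)) for i in matrix.index]
    return pd.DataFrame([p.__dict__ for p in profs]).set_index(
        "individual_id", drop=False
    )


def summarize_introgression(profiles: pd.DataFrame, depths) -> pd.DataFrame:
    """Depth-stratified introgression table.

    Per depth: n, % of individuals carrying at least one MT allele, counts per
    MT_AF bin, and means of MT_AF, H_O and HI over *all* individuals at the
    depth (zeros included), plus a pooled "all" row.  The identity
    mean(MT_AF) = mean(HI) - mean(H_O)/2 holds exactly.
    """
    df = profiles.copy()
    depth_map = depths if hasattr(depths, "get") else dict(depths)
    df["depth_m"] = [depth_map[i] for i in df["individual_id"]]

    def _row(sub: pd.DataFrame, label) -> dict:
        n = len(sub)
        pos = int((sub["nXY"] + sub["nXX"] > 0).sum())
        out = {
            "depth": label,
            "n": n,
            "mt_positive": pos,
            "pct_mt_positive": 100.0 * pos / n,
        }
        for b in BIN_LABELS[1:]:
            out[f"bin_{b}"] = int((sub["bin"] == b).sum())
        out["mean_MT_AF"] = sub["MT_AF"].mean()
        out["mean_H_O"] = sub["H_O"].mean()
        out["mean_HI"] = sub["HI"].mean()
        return out

    rows = [_row(g, d) for d, g in df.groupby("depth_m")]
    rows.append(_row(df, "all"))
    return pd.DataFrame(rows)


def maf_detection_limit(n_chromosomes: int) -> float:
    """Lowest minor allele frequency detectable in a discovery sample.

    One allele copy among ``n_chromosomes`` sequenced chromosomes: 1/n.
    With 72 ME/MG chromosomes this is ~1.4%; with 8 MT chromosomes, 12.5% —
    the frequencies below which a "diagnostic" call may simply be leakage.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    return 1.0 / n_chromosomes


def cluster_heatmap_order(matrix: pd.DataFrame):
    """Leaf orders for a genotype heatmap (rows = individuals, cols = loci).

    Agglomerative hierarchical clustering, Euclidean distance, complete
    linkage, on rows and columns separately; missing cells are imputed as 0
    for the distance computation only.  Returns (row_order, col_order) as
    integer position arrays.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty matrix")

    def _order(arr: np.ndarray) -> np.ndarray:
        if arr.shape[0] == 1:
            return np.array([0])
        z = linkage(pdist(arr, metric="euclidean"), method="complete")
        return leaves_list(z)

    filled = matrix.fillna(0.0).to_numpy(dtype=float)
    return _order(filled), _order(filled.T)


def concordance_me1516_snp(calls, profiles: pd.DataFrame):
    """Cross-tabulate Me15/16 species class against SNP MT_AF bands.

    Bands: MT_AF < 0.1, 0.1-0.3, > 0.3.  An individual is discordant when the
    two markers disagree strongly: MT_AF >= 0.3 but no MT fragment, or an MT
    fragment but MT_AF < 0.1.  Returns (table, discordance DataFrame).
    """
    calls = list(calls)
    call_ids = {c.individual_id for c in calls}
    prof_ids = set(profiles["individual_id"])
    missing = sorted(call_ids ^ prof_ids)
    if missing:
        raise ValueError(f"unmatched individual ids: {missing}")
    if not calls:
        return pd.DataFrame(), pd.DataFrame(
            columns=["individual_id", "species_class", "MT_AF", "reason"]
        )
    mt_af = profiles.set_index("individual_id")["MT_AF"]
    band = pd.cut(
        mt_af,
        bins=[-np.inf, 0.1, 0.3, np.inf],
        labels=["<0.1", "0.1-0.3", ">0.3"],
        right=False,
    )
    cls = pd.Series({c.individual_id: c.species_class for c in calls})
    table = pd.crosstab(cls, band.reindex(cls.index))
    disc = []
    for c in calls:
        af = float(mt_af[c.individual_id])
        has_mt = "MT" in c.species_class.split("×") or c.species_class == "MT"
        if af >= 0.3 and not has_mt and c.species_class != "UNDETERMINED":
            disc.append((c.individual_id, c.species_class, af, "snp_mt_no_fragment"))
        elif has_mt and af < 0.1:
            disc.append((c.individual_id, c.species_class, af, "fragment_mt_low_snp"))
    disc_df = pd.DataFrame(
        disc, columns=["individual_id", "species_class", "MT_AF", "reason"]
    )
    return table, disc_df
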