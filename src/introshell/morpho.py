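"""Outline morphometrics of shell valves via elliptic Fourier analysis.

Pipeline: binary valve mask -> ordered boundary trace -> arc-length uniform
resampling and centring -> Kuhl-Giardina elliptic Fourier decomposition ->
first-harmonic normalisation (rotation, scale and starting-point invariant)
-> harmonic-power truncation -> PCA of the coefficient matrix -> MANOVA of
the retained shape axes against depth or introgression groups.

Conventions: outline coordinates are pixel-centre based with the y axis
pointing up; traversal is counterclockwise; closure is implicit (the first
point is not repeated).  After normalisation the first harmonic satisfies
a1 = 1 (size standardised by the semi-major axis), b1 = 0 and c1 = 0; the
residual 180-degree starting-point ambiguity is resolved by the sign of the
first non-negligible even-harmonic coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EFACoefficients",
    "ShapeSpace",
    "MANOVAResult",
    "trace_outline",
    "preprocess_outline",
    "efa_decompose",
    "efa_normalize",
    "harmonic_power",
    "choose_harmonics",
    "efa_reconstruct",
    "coefficient_matrix",
    "shape_pca",
    "manova_wilks",
    "pairwise_manova",
    "mean_shape",
]


# ---------------------------------------------------------------------------
# boundary tracing

# Moore neighbourhood in clockwise order, starting north, as (dr, dc)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_outline(image: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a single foreground component.

    Moore-neighbour tracing with Jacob's stopping criterion on an 8-connected
    component; interior holes are ignored.  Returns an (n, 2) array of (x, y)
    pixel coordinates (x = column, y = row, so y increases upward when row 0
    is the image bottom), closed implicitly, counterclockwise.
    """
    from skimage.measure import label

    img = np.asarray(image).astype(bool)
    labels, n_comp = label(img, connectivity=2, return_num=True)
    if n_comp != 1:
        raise ValueError(f"expected exactly 1 foreground component, found {n_comp}")

    rows, cols = np.nonzero(img)
    start = (rows.min(), cols[rows == rows.min()].min())

    def fg(p):
        r, c = p
        return 0 <= r < img.shape[0] and 0 <= c < img.shape[1] and img[r, c]

    boundary = [start]
    backtrack = (start[0], start[1] - 1)  # entered scanning west-to-east
    cur = start
    for _ in range(4 * img.size):
        k = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for j in range(1, 9):
            cand = _MOORE[(k + j) % 8]
            p = (cur[0] + cand[0], cur[1] + cand[1])
            if fg(p):
                nxt = p
                backtrack = (
                    cur[0] + _MOORE[(k + j - 1) % 8][0],
                    cur[1] + _MOORE[(k + j - 1) % 8][1],
                )
                break
        if nxt is None or nxt == start:  # isolated pixel, or back home
            break
        boundary.append(nxt)
        cur = nxt
    else:
        raise RuntimeError("boundary trace did not terminate")
    if boundary[-1] == start:
        boundary.pop()
    if len(boundary) < 32:
        raise ValueError(
            f"component boundary has {len(boundary)} pixels, need at least 32"
        )
    xy = np.array([(c, r) for r, c in boundary], dtype=float)
    if _signed_area(xy) < 0:
        xy = np.vstack([xy[:1], xy[:0:-1]])
    return xy


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_outline(outline: np.ndarray, n_points: int = 300) -> np.ndarray:
    """Resample to ``n_points`` uniform arc-length steps, centre, force CCW."""
    xy = np.asarray(outline, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
        raise ValueError("outline must be an (n >= 3, 2) array")
    closed = np.vstack([xy, xy[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    perim = seg.sum()
    if perim <= 0:
        raise ValueError("degenerate outline: zero perimeter")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, perim, n_points, endpoint=False)
    res = np.column_stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])]
    )
    res -= res.mean(axis=0)
    if _signed_area(res) < 0:
        res = np.vstack([res[:1], res[:0:-1]])
    return res


# ---------------------------------------------------------------------------
# elliptic Fourier analysis


@dataclass(frozen=True)
class EFACoefficients:
    """Elliptic Fourier coefficients: harmonics 1..N of x(t) and y(t).

    ``a``, ``b`` are the cosine/sine coefficients of x(t); ``c``, ``d`` of
    y(t); ``A0``, ``C0`` the offsets.  ``normalized`` marks first-harmonic
    standardisation (rotation/scale/start-point invariant).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    A0: float = 0.0
    C0: float = 0.0
    normalized: bool = False

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def as_matrix(self) -> np.ndarray:
        """(N, 4) array of rows (a_n, b_n, c_n, d_n)."""
        return np.column_stack([self.a, self.b, self.c, self.d])


def efa_decompose(
    outline: np.ndarray, n_harmonics: int, spacing: str = "uniform"
) -> EFACoefficients:
    """Kuhl-Giardina chain-integral coefficients of a closed outline.

    The outline is treated as piecewise linear in the curve parameter t.
    With ``spacing="uniform"`` (default) the vertices are taken as uniformly
    spaced in t — exact for outlines resampled by :func:`preprocess_outline`
    and for parametric curves sampled at uniform parameter steps, so an exact
    ellipse is represented by harmonic 1 alone.  ``spacing="arc"`` uses the
    classical chain-length parametrisation instead.
    """
    xy = np.asarray(outline, dtype=float)
    if not (1 <= n_harmonics <= len(xy) // 2):
        raise ValueError(
            f"n_harmonics must be in [1, n_points/2], got {n_harmonics} "
            f"for {len(xy)} points"
        )
    if spacing not in ("uniform", "arc"):
        raise ValueError("spacing must be 'uniform' or 'arc'")
    dxy = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    dt = np.hypot(dxy[:, 0], dxy[:, 1])
    if (dt == 0).any():
        keep = dt > 0
        dxy, dt = dxy[keep], dt[keep]
    if spacing == "uniform":
        dt = np.full(len(dxy), 1.0)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T

    n = np.arange(1, n_harmonics + 1)[:, None]
    const = T / (2.0 * n**2 * np.pi**2)
    d_cos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    d_sin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    vx = dxy[:, 0] / dt
    vy = dxy[:, 1] / dt
    a = (const * (vx[None, :] * d_cos)).sum(axis=1)
    b = (const * (vx[None, :] * d_sin)).sum(axis=1)
    c = (const * (vy[None, :] * d_cos)).sum(axis=1)
    d = (const * (vy[None, :] * d_sin)).sum(axis=1)

    # offsets
    xi = np.cumsum(dxy[:, 0]) - vx * t[1:]
    a0 = (1.0 / T) * np.sum(vx / 2.0 * np.diff(t**2) + xi * np.diff(t))
    delta = np.cumsum(dxy[:, 1]) - vy * t[1:]
    c0 = (1.0 / T) * np.sum(vy / 2.0 * np.diff(t**2) + delta * np.diff(t))
    return EFACoefficients(
        a=a, b=b, c=c, d=d, A0=float(xy[0, 0] + a0), C0=float(xy[0, 1] + c0)
    )


def _rotate_start(coeffs: EFACoefficients, theta: float) -> EFACoefficients:
    """Shift the starting point by phase ``theta`` (coefficient-space rotation)."""
    a, b, c, d = (np.array(v, dtype=float) for v in (coeffs.a, coeffs.b, coeffs.c, coeffs.d))
    for i in range(coeffs.n_harmonics):
        n = i + 1
        cn, sn = np.cos(n * theta), np.sin(n * theta)
        rot = np.array([[cn, -sn], [sn, cn]])
        m = np.array([[a[i], b[i]], [c[i], d[i]]]) @ rot
        a[i], b[i], c[i], d[i] = m.ravel()
    return replace(coeffs, a=a, b=b, c=c, d=d)


def _rotate_space(coeffs: EFACoefficients, psi: float) -> EFACoefficients:
    """Rotate the outline itself by ``-psi`` (align semi-major axis with x)."""
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    m = np.einsum("ij,njk->nik", rot, np.stack(
        [np.column_stack([coeffs.a, coeffs.b]), np.column_stack([coeffs.c, coeffs.d])],
        axis=1,
    ))
    return replace(coeffs, a=m[:, 0, 0], b=m[:, 0, 1], c=m[:, 1, 0], d=m[:, 1, 1])


def efa_normalize(coeffs: EFACoefficients) -> EFACoefficients:
    """First-harmonic standardisation of elliptic Fourier coefficients.

    Removes starting point (phase rotation so the trace starts on the first
    harmonic's semi-major axis), outline rotation (semi-major axis aligned
    with +x) and size (all coefficients divided by the semi-major axis
    length); the offset is zeroed.  The remaining half-turn ambiguity is
    resolved by requiring the first even-harmonic coefficient exceeding
    1e-9 in either candidate to be positive, so identical shapes always map
    to identical coefficients.
    """
    a1, b1, c1, d1 = coeffs.a[0], coeffs.b[0], coeffs.c[0], coeffs.d[0]
    if a1**2 + b1**2 + c1**2 + d1**2 < 1e-300:
        raise ValueError("degenerate first harmonic")
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 - b1**2 + c1**2 - d1**2
    )

    def _candidate(th: float) -> EFACoefficients:
        out = _rotate_start(coeffs, th)
        psi = np.arctan2(out.c[0], out.a[0])
        out = _rotate_space(out, psi)
        scale = out.a[0]
        if scale <= 0:
            # semi-major magnitude is positive after psi alignment by construction
            raise RuntimeError("normalisation scale must be positive")
        return replace(
            out,
            a=out.a / scale,
            b=out.b / scale,
            c=out.c / scale,
            d=out.d / scale,
            A0=0.0,
            C0=0.0,
            normalized=True,
        )

    cand1 = _candidate(theta)
    if cand1.n_harmonics == 1:
        return cand1
    cand2 = _candidate(theta + np.pi)
    # candidates differ only in the sign of even harmonics; pick deterministically
    for i in range(1, cand1.n_harmonics, 2):  # even harmonic numbers (index 1 = n2)
        for arr1, arr2 in (
            (cand1.a, cand2.a),
            (cand1.b, cand2.b),
            (cand1.c, cand2.c),
            (cand1.d, cand2.d),
        ):
            if max(abs(arr1[i]), abs(arr2[i])) > 1e-9:
                return cand1 if arr1[i] > 0 else cand2
    return cand1


def harmonic_power(coeffs: EFACoefficients) -> np.ndarray:
    """Cumulative shares of harmonic power (a^2+b^2+c^2+d^2)/2 per harmonic."""
    if coeffs.n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    power = (coeffs.a**2 + coeffs.b**2 + coeffs.c**2 + coeffs.d**2) / 2.0
    return np.cumsum(power) / power.sum()


def choose_harmonics(cumulative_shares: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest harmonic count whose cumulative power share exceeds threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    shares = np.asarray(cumulative_shares, dtype=float)
    idx = np.nonzero(shares > threshold)[0]
    if len(idx) == 0:
        return len(shares)
    return int(idx[0]) + 1


def efa_reconstruct(coeffs: EFACoefficients, n_points: int = 300) -> np.ndarray:
    """Inverse Fourier synthesis of the outline at ``n_points`` samples."""
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cosnt = np.cos(n * t)
    sinnt = np.sin(n * t)
    x = coeffs.A0 + (coeffs.a[:, None] * cosnt + coeffs.b[:, None] * sinnt).sum(axis=0)
    y = coeffs.C0 + (coeffs.c[:, None] * cosnt + coeffs.d[:, None] * sinnt).sum(axis=0)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# shape space


def coefficient_matrix(
    coeff_list: list[EFACoefficients], ids=None, drop_constant: bool = True
) -> pd.DataFrame:
    """Stack per-individual coefficients into an individuals x variables frame.

    For normalised coefficients, the entries fixed by the alignment
    convention (a1 = 1, b1 = 0, c1 = 0) carry no shape information and are
    dropped by default, leaving d1 plus harmonics 2..N.
    """
    if not coeff_list:
        raise ValueError("empty coefficient list")
    n_h = coeff_list[0].n_harmonics
    if any(c.n_harmonics != n_h for c in coeff_list):
        raise ValueError("all individuals must have the same harmonic count")
    cols = []
    for n in range(1, n_h + 1):
        cols += [f"a{n}", f"b{n}", f"c{n}", f"d{n}"]
    data = np.array([c.as_matrix().ravel() for c in coeff_list])
    df = pd.DataFrame(data, columns=cols, index=ids)
    if drop_constant and all(c.normalized for c in coeff_list):
        df = df.drop(columns=["a1", "b1", "c1"])
    return df


@dataclass
class ShapeSpace:
    """PCA of the shape-coefficient matrix."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_shares: np.ndarray
    n_retained: int
    mean_: pd.Series

    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_retained]


def shape_pca(coeff_df: pd.DataFrame, retain_threshold: float = 0.95) -> ShapeSpace:
    """Centred (unscaled) PCA of shape coefficients.

    Retains the smallest number of PCs whose cumulative variance share
    exceeds ``retain_threshold``.
    """
    if len(coeff_df) < 3:
        raise ValueError("need at least 3 individuals for a shape PCA")
    from sklearn.decomposition import PCA

    pca = PCA()
    scores = pca.fit_transform(coeff_df.to_numpy(dtype=float))
    shares = pca.explained_variance_ratio_
    n_ret = int(np.searchsorted(np.cumsum(shares), retain_threshold) + 1)
    n_ret = min(n_ret, len(shares))
    pc_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return ShapeSpace(
        scores=pd.DataFrame(scores, index=coeff_df.index, columns=pc_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=coeff_df.columns, columns=pc_names
        ),
        variance_shares=shares,
        n_retained=n_ret,
        mean_=pd.Series(pca.mean_, index=coeff_df.columns),
    )


# ---------------------------------------------------------------------------
# MANOVA


@dataclass(frozen=True)
class MANOVAResult:
    wilks_lambda: float
    approx_f: float
    df1: float
    df2: float
    p_value: float
    n: int


def manova_wilks(scores: pd.DataFrame, grouping, kind: str = "auto") -> MANOVAResult:
    """Wilks' Lambda MANOVA of shape variables on a factor or covariate.

    ``grouping`` may be categorical (group labels -> one-way MANOVA) or
    numeric (continuous covariate -> multivariate regression test of its
    single df); ``kind`` forces the treatment ("factor" / "covariate") when
    the automatic choice (non-numeric or few distinct values -> factor) is
    not wanted.  Lambda = det(E)/det(E+H) from the error and hypothesis
    cross-product matrices; the F approximation is Rao's.
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    g = np.asarray(grouping)
    n, p = y.shape
    if len(g) != n:
        raise ValueError("grouping must align with scores")
    if kind not in ("auto", "factor", "covariate"):
        raise ValueError("kind must be 'auto', 'factor' or 'covariate'")
    if kind == "auto":
        numeric = np.issubdtype(g.dtype, np.number)
        kind = (
            "covariate"
            if numeric and len(np.unique(g)) > max(6, n // 10)
            else "factor"
        )
    if kind == "covariate":
        if not np.issubdtype(g.dtype, np.number):
            raise ValueError("covariate treatment needs numeric grouping")
        X = np.column_stack([np.ones(n), g.astype(float)])
        q = 1
    else:
        levels = pd.unique(g)
        if len(levels) < 2:
            raise ValueError("need at least two groups")
        X = np.column_stack(
            [np.ones(n)] + [(g == lv).astype(float) for lv in levels[1:]]
        )
        q = len(levels) - 1
    X0 = X[:, :1]

    def _resid_sscp(Xd):
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        r = y - Xd @ beta
        return r.T @ r

    E = _resid_sscp(X)
    E0 = _resid_sscp(X0)
    H = E0 - E
    sign, logdet_e = np.linalg.slogdet(E)
    if sign <= 0:
        raise ValueError(
            "singular within-group cross-product matrix; retain fewer PCs"
        )
    _, logdet_t = np.linalg.slogdet(E + H)
    lam = float(np.exp(logdet_e - logdet_t))

    v = n - X.shape[1]  # error df
    s = (
        np.sqrt((p**2 * q**2 - 4.0) / (p**2 + q**2 - 5.0))
        if p**2 + q**2 - 5 > 0
        else 1.0
    )
    m = v - (p - q + 1.0) / 2.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f = ((1.0 - lam_s) / lam_s) * (df2 / df1) if lam_s > 0 else np.inf
    pval = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return MANOVAResult(
        wilks_lambda=lam, approx_f=float(f), df1=float(df1), df2=float(df2),
        p_value=pval, n=n,
    )


def pairwise_manova(
    scores: pd.DataFrame, groups, bonferroni: bool = False
) -> pd.DataFrame:
    """MANOVA for every pair of group levels (no pooled correction).

    Raw p-values by default, matching the convention of reporting raw
    pairwise approximate F values; an optional Bonferroni column is added
    when requested.
    """
    g = pd.Series(np.asarray(groups), index=scores.index)
    levels = list(pd.unique(g))
    rows = []
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    for a, b in pairs:
        mask = g.isin([a, b]).to_numpy()
        res = manova_wilks(scores.loc[mask], g[mask].to_numpy())
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "wilks_lambda": res.wilks_lambda,
                "approx_f": res.approx_f,
                "df1": res.df1,
                "df2": res.df2,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if bonferroni and len(out):
        out["p_bonferroni"] = np.minimum(out["p_value"] * len(pairs), 1.0)
    return out


def mean_shape(
    coeffs_by_group: dict, n_points: int = 300
) -> dict:
    """Arithmetic mean of coefficients per group, reconstructed as outlines."""
    shapes = {}
    for group, members in coeffs_by_group.items():
        members = list(members)
        if not members:
            raise ValueError(f"empty group {group!r}")
        mean_coeffs = EFACoefficients(
            a=np.mean([m.a for m in members], axis=0),
            b=np.mean([m.b for m in members], axis=0),
            c=np.mean([m.c for m in members], axis=0),
            d=np.mean([m.d for m in members], axis=0),
            A0=float(np.mean([m.A0 for m in members])),
            C0=float(np.mean([m.C0 for m in members])),
            normalized=all(m.normalized for m in members),
        )
        shapes[group] = efa_reconstruct(mean_coeffs, n_points)
    return shapes
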