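#!/usr/bin/env python
"""Shell shape: elliptic Fourier analysis, shape PCA and MANOVA.

Builds a valve outline per individual from its simulated elongation (SL:SH),
decomposes outlines into normalised elliptic Fourier coefficients, truncates
the series by the >95% harmonic-power rule, runs a centred PCA of the
coefficient matrix, and tests shape differences across depth and MT
introgression groups (none / low / high) with Wilks' Lambda MANOVAs.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from introshell import morpho, syndata


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--noise-sd", type=float, default=0.02)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    shells = pd.read_csv(args.cohort / "shells.csv").set_index(
        "individual_id", drop=False
    )
    ratio = shells["SL_mm"] / shells["SH_mm"]

    coeffs = []
    for i, (ind, r) in enumerate(ratio.items()):
        o = syndata.simulate_outline(float(r), 300, args.noise_sd,
                                     seed=args.seed * 100_003 + i)
        p = morpho.preprocess_outline(o, 300)
        coeffs.append(morpho.efa_normalize(morpho.efa_decompose(p, 16)))

    shares = np.mean([morpho.harmonic_power(c) for c in coeffs], axis=0)
    n_h = morpho.choose_harmonics(shares, 0.95)
    print(f"{n_h} harmonics carry >95% of mean harmonic power "
          f"(cumulative share {shares[n_h - 1]:.4f})")

    cmat = morpho.coefficient_matrix(coeffs, ids=shells.index)
    cmat.to_csv(args.outdir / "efa_coefficients.csv")
    space = morpho.shape_pca(cmat, retain_threshold=0.95)
    space.scores.to_csv(args.outdir / "shape_pc_scores.csv")
    print(f"PC1 explains {100 * space.variance_shares[0]:.1f}% of shape "
          f"variation; {space.n_retained} PCs retained (>95%)")

    scores = space.retained_scores()
    res_depth = morpho.manova_wilks(
        scores, shells["depth_m"].to_numpy(), kind="covariate"
    )
    res_mt = morpho.manova_wilks(
        scores, shells["mt_af"].to_numpy(), kind="covariate"
    )
    print(f"MANOVA shape ~ depth: Wilks' Lambda = {res_depth.wilks_lambda:.2f}, "
          f"approx. F = {res_depth.approx_f:.1f}, p = {res_depth.p_value:.2g}")
    print(f"MANOVA shape ~ MT_AF: Wilks' Lambda = {res_mt.wilks_lambda:.2f}, "
          f"approx. F = {res_mt.approx_f:.1f}, p = {res_mt.p_value:.2g}")
    pd.DataFrame([
        {"effect": "depth", **res_depth.__dict__},
        {"effect": "mt_af", **res_mt.__dict__},
    ]).to_csv(args.outdir / "shape_manova.csv", index=False)

    pw = morpho.pairwise_manova(scores, shells["depth_m"].to_numpy())
    pw.to_csv(args.outdir / "shape_manova_pairwise_depth.csv", index=False)
    worst = pw.loc[pw["approx_f"].idxmax()]
    print(f"pairwise depth MANOVA: largest contrast "
          f"{worst['group_a']} m vs {worst['group_b']} m "
          f"(approx. F = {worst['approx_f']:.1f})")

    mt_group = pd.cut(
        shells["mt_af"], [-np.inf, 1e-12, 0.75, np.inf],
        labels=["none", "low", "high"],
    )
    groups = {
        g: [coeffs[k] for k in np.flatnonzero((mt_group == g).to_numpy())]
        for g in ("none", "low", "high")
        if (mt_group == g).any()
    }
    shapes = morpho.mean_shape(groups, n_points=300)
    for g, xy in shapes.items():
        pd.DataFrame(xy, columns=["x", "y"]).to_csv(
            args.outdir / f"mean_shape_{g}.csv", index=False
        )
        print(f"mean shape [{g:4s}]: bounding-box elongation "
              f"{np.ptp(xy[:, 0]) / np.ptp(xy[:, 1]):.2f}")


if __name__ == "__main__":
    main()
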