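"""Image-quality and method-agreement statistics.

SSIM for image fidelity, Bland-Altman limits of agreement and Spearman rank
correlation for comparing atrophy scores between imaging conditions, and
linearly weighted Cohen's kappa for ordinal (5-point Likert) rating
agreement.  ``evaluate_suite`` ties them together into per-condition report
tables for artifact, U-Net-corrected and Pix2Pix-corrected images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from . import atrophy as at
from .kspace import TEST_PATTERNS, MotionPattern, PairedSample

__all__ = ["AgreementStats", "ssim", "bland_altman", "spearman_rho",
           "weighted_kappa", "evaluate_suite"]


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of differences d = x - y."""

    mean_bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity with Gaussian 11x11 weighting, sigma 1.5.

    Uses the canonical constants K1=0.01, K2=0.03 and population (not
    sample) local covariances, i.e. the original SSIM definition.  The
    dynamic range defaults to the joint max-min of the pair.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        if data_range == 0:
            return 1.0
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False))


def bland_altman(x, y) -> AgreementStats:
    """Mean bias and mean ± 1.96 SD limits of agreement of d = x - y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(mean_bias=bias, loa_low=bias - 1.96 * sd,
                          loa_high=bias + 1.96 * sd, sd_diff=sd, n=d.size)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mean ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def weighted_kappa(r1, r2, n_categories: int = 5,
                   weights: str = "linear") -> float:
    """Weighted Cohen's kappa for two raters on a shared ordinal scale.

    Ratings are integers in 1..n_categories; linear weights by default,
    quadratic available.  kappa = 1 - sum(w*O) / sum(w*E).
    """
    r1 = np.asarray(r1, dtype=int)
    r2 = np.asarray(r2, dtype=int)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rating vectors must be 1-D and of equal length")
    if r1.size == 0:
        raise ValueError("empty ratings")
    cats = np.arange(1, n_categories + 1)
    if not (np.isin(r1, cats).all() and np.isin(r2, cats).all()):
        raise ValueError(f"ratings must lie in 1..{n_categories}")
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    k = n_categories
    obs = np.zeros((k, k))
    for a, b in zip(r1, r2):
        obs[a - 1, b - 1] += 1
    obs /= obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(ii - jj).astype(float)
    if weights == "quadratic":
        w = w ** 2
    denom = (w * exp).sum()
    if denom == 0:
        return 1.0
    return float(1.0 - (w * obs).sum() / denom)


def _group_pairs(pairs: list[PairedSample]):
    by_pat: dict[str, dict[int, list[PairedSample]]] = {}
    for p in pairs:
        by_pat.setdefault(p.pattern.label, {}).setdefault(p.volume_id, []).append(p)
    for vols in by_pat.values():
        for lst in vols.values():
            lst.sort(key=lambda s: s.slice_index)
    return by_pat


def _stack(samples: list[PairedSample], which: str) -> np.ndarray:
    return np.stack([getattr(s, which) for s in samples])


def evaluate_suite(test_pairs: list[PairedSample], models: dict,
                   normative: at.NormativeModel, volumes: dict | None = None,
                   patterns: tuple[MotionPattern, ...] = TEST_PATTERNS,
                   out_dir=None):
    """Per-condition SSIM and atrophy-score agreement report.

    Parameters
    ----------
    test_pairs
        (artifact, original) pairs for the evaluation conditions.
    models
        Mapping of method name (e.g. ``"unet"``, ``"pix2pix"``) to a trained
        model exposing ``correct(image) -> image``.
    normative
        Normative model fit on control stacks matching the retained-slice
        stacks assembled here.
    volumes
        Mapping ``volume_id -> PhantomVolume`` supplying GM/VOI masks for
        atrophy scoring (required for the agreement tables).
    patterns
        Conditions to report; defaults to the four trained + two held-out.

    Returns a dict with ``ssim`` and ``agreement`` DataFrames; writes
    ``table_ssim.csv``, ``table_agreement.csv`` and Bland-Altman scatter
    plots when ``out_dir`` is given.
    """
    wanted = {p.label for p in patterns}
    by_pat = _group_pairs([p for p in test_pairs if p.pattern.label in wanted])
    missing = wanted - set(by_pat)
    if missing:
        raise ValueError(f"no pairs for patterns: {sorted(missing)}")
    method_names = list(models)

    ssim_rows, score_rows = [], []
    for pat in patterns:
        lab = pat.label
        vols = by_pat[lab]
        per_method = {"artifact": [], **{m: [] for m in method_names}}
        for vol_id, samples in sorted(vols.items()):
            orig = _stack(samples, "original")
            arts = _stack(samples, "artifact")
            corrected = {m: np.stack([models[m].correct(a) for a in arts])
                         for m in method_names}
            for o, a in zip(orig, arts):
                per_method["artifact"].append(ssim(a, o))
            for m in method_names:
                for o, c in zip(orig, corrected[m]):
                    per_method[m].append(ssim(c, o))
            if volumes is not None:
                vol = volumes[vol_id]
                idx = [s.slice_index for s in samples]
                gm = vol.gm_mask[idx]
                voi = vol.voi_mask[idx]
                conds = {"original": orig, "artifact": arts, **corrected}
                for cond, stack in conds.items():
                    sc = at.score_volume(stack, normative, gm_mask=gm,
                                         voi_mask=voi)
                    score_rows.append({
                        "pattern": lab, "volume_id": vol_id, "method": cond,
                        "severity_voi": sc.severity_voi,
                        "extent_gm": sc.extent_gm,
                        "extent_voi": sc.extent_voi})
        for m, vals in per_method.items():
            ssim_rows.append({"pattern": lab, "method": m,
                              "ssim_mean": float(np.mean(vals)),
                              "ssim_sd": float(np.std(vals, ddof=1))
                              if len(vals) > 1 else 0.0,
                              "n": len(vals)})

    ssim_table = pd.DataFrame(ssim_rows)
    agreement_table = None
    scores = pd.DataFrame(score_rows) if score_rows else None
    if scores is not None:
        agr_rows = []
        for pat in patterns:
            lab = pat.label
            sub = scores[scores.pattern == lab].set_index(["method", "volume_id"])
            ref = sub.loc["original"].sort_index()
            for m in ["artifact", *method_names]:
                cur = sub.loc[m].sort_index()
                for sc in ("severity_voi", "extent_gm", "extent_voi"):
                    x = cur[sc].to_numpy()
                    y = ref[sc].to_numpy()
                    ba = bland_altman(x, y)
                    try:
                        rho, pval = spearman_rho(x, y)
                    except ValueError:
                        rho, pval = np.nan, np.nan
                    agr_rows.append({
                        "pattern": lab, "method": m, "score": sc,
                        "mean_bias": ba.mean_bias, "loa_low": ba.loa_low,
                        "loa_high": ba.loa_high, "rho": rho, "p": pval,
                        "n": ba.n})
        agreement_table = pd.DataFrame(agr_rows)

    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ssim_table.to_csv(out / "table_ssim.csv", index=False)
        if agreement_table is not None:
            agreement_table.to_csv(out / "table_agreement.csv", index=False)
            _plot_bland_altman(scores, method_names, out)
    return {"ssim": ssim_table, "agreement": agreement_table,
            "scores": scores}


def _plot_bland_altman(scores: pd.DataFrame, method_names, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for sc in ("severity_voi", "extent_gm", "extent_voi"):
        fig, axes = plt.subplots(1, 1 + len(method_names), figsize=(
            4 * (1 + len(method_names)), 3.5), squeeze=False)
        for ax, m in zip(axes[0], ["artifact", *method_names]):
            pivot = scores.pivot_table(index=["pattern", "volume_id"],
                                       columns="method", values=sc)
            x = pivot[m].to_numpy()
            y = pivot["original"].to_numpy()
            ba = bland_altman(x, y)
            ax.scatter((x + y) / 2, x - y, s=12)
            for yline, style in ((ba.mean_bias, "-"), (ba.loa_low, "--"),
                                 (ba.loa_high, "--")):
                ax.axhline(yline, ls=style, c="k", lw=0.8)
            ax.set_title(f"{m}: {sc}")
            ax.set_xlabel("mean")
            ax.set_ylabel("difference")
        fig.tight_layout()
        fig.savefig(f"{out_dir}/bland_altman_{sc}.png", dpi=110)
        plt.close(fig)
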