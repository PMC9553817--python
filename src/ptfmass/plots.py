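"""Validation figures: regression, Bland-Altman and ROC panels."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import AgreementResult, PairedMeasurements, RocResult, bland_altman  # noqa: E402


def plot_agreement(pm: PairedMeasurements, path, label_a: str = "PET",
                   label_b: str = "reference", unit: str = "") -> AgreementResult:
    """Two-panel figure: identity-line regression and Bland-Altman with LoA."""
    res = bland_altman(pm)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(pm.b, pm.a, s=18, alpha=0.8)
    lim = [min(pm.a.min(), pm.b.min()), max(pm.a.max(), pm.b.max())]
    ax1.plot(lim, lim, "k:", lw=1, label="identity")
    xs = np.linspace(*lim, 2)
    ax1.plot(xs, res.slope * xs + res.intercept, "-", lw=1.2,
             label=f"fit (r={res.r:.2f})")
    ax1.set_xlabel(f"{label_b} {unit}".strip())
    ax1.set_ylabel(f"{label_a} {unit}".strip())
    ax1.legend(frameon=False, fontsize=8)

    mean = 0.5 * (pm.a + pm.b)
    diff = pm.a - pm.b
    ax2.scatter(mean, diff, s=18, alpha=0.8)
    for y, style in [(res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")]:
        ax2.axhline(y, color="k", ls=style, lw=1)
    ax2.set_xlabel(f"mean {unit}".strip())
    ax2.set_ylabel(f"{label_a} - {label_b} {unit}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res


def plot_roc(scores: np.ndarray, truth: np.ndarray, res: RocResult, path) -> None:
    """Empirical ROC curve with the Youden operating point marked."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    cuts = np.r_[-np.inf, np.unique(scores)]
    sens = [(scores[truth] > c).mean() for c in cuts]
    fpr = [(scores[~truth] > c).mean() for c in cuts]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(fpr, sens, drawstyle="steps-post", lw=1.5)
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.plot(1 - res.specificity, res.sensitivity, "o", ms=7,
            label=f"cutoff {res.best_cutoff:.3g}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {res.auc:.3f}")
    ax.legend(frameon=False, fontsize=8, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
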