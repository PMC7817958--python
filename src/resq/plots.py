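"""Static figures: forest plot of factor effects, LASSO coefficient paths."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["forest_plot", "coefficient_path_plot"]


def forest_plot(fits: dict[str, dict], path: str | None = None):
    """Coefficients with CIs for the directed factor hypotheses."""
    names = list(fits)
    betas = [fits[f]["beta"] for f in names]
    lows = [fits[f]["ci_low"] for f in names]
    highs = [fits[f]["ci_high"] for f in names]
    ypos = np.arange(len(names))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(names) + 1.2))
    ax.errorbar(
        betas, ypos,
        xerr=[np.subtract(betas, lows), np.subtract(highs, betas)],
        fmt="o", color="tab:blue", ecolor="black", capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels([n.upper() for n in names])
    ax.set_xlabel("standardized coefficient (99% CI)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def coefficient_path_plot(
    coef_path: pd.DataFrame, lambda_opt: float, factors: list[str] | None = None,
    path: str | None = None,
):
    """Coefficient trajectories over the penalty grid (factors in color,
    covariates in grey), with the selected lambda marked."""
    lams = np.asarray(coef_path.columns, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    factors = factors or []
    for term in coef_path.index:
        kwargs = {"lw": 1.6} if term in factors else {"color": "grey", "lw": 0.8, "alpha": 0.6}
        ax.plot(lams, coef_path.loc[term], label=term if term in factors else None, **kwargs)
    ax.axvline(lambda_opt, ls="--", color="black", lw=1)
    ax.set_xscale("log")
    ax.invert_xaxis()
    ax.set_xlabel("penalty λ (log scale)")
    ax.set_ylabel("standardized coefficient")
    if factors:
        ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
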