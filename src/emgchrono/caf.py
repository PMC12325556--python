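"""Conditional accuracy functions (CAFs).

Responded trials are rank-ordered by RT within participant x bias-block x
lexicality cells and divided into k (default 5) near-equal quantile bins;
accuracy, mean RT and mean EMG onset are summarized per bin.  Orthonormal
polynomial scores over the bin index provide the linear/quadratic quantile
covariates for the CAF mixed model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_CELL = ("participant_id", "block", "lexicality")


def bin_quantiles(
    trials: pd.DataFrame,
    k: int = 5,
    cell: tuple[str, ...] = DEFAULT_CELL,
    rt_col: str = "rt",
) -> pd.DataFrame:
    """Assign RT-quantile bins (1..k) within each cell.

    Trials are sorted by RT (ties broken by original row order) and split
    into k bins whose sizes differ by at most one; with n = q*k + r the first
    r bins receive the extra trial.  Cells with fewer than k trials fall back
    to a single bin with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = trials.copy()
    out["quantile"] = 0

    def sizes(n: int) -> np.ndarray:
        q, r = divmod(n, k)
        return np.array([q + 1] * r + [q] * (k - r))

    for key, idx in out.groupby(list(cell), observed=True, sort=False).groups.items():
        n = len(idx)
        order = out.loc[idx].sort_values(rt_col, kind="stable").index
        if n < k:
            warnings.warn(f"cell {key}: {n} trials < {k} quantiles; single bin used")
            out.loc[idx, "quantile"] = 1
            continue
        bins = np.repeat(np.arange(1, k + 1), sizes(n))
        out.loc[order, "quantile"] = bins
    return out


def polynomial_scores(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal linear and quadratic contrasts over bin indices 1..k:
    zero-sum, unit-norm, mutually orthogonal."""
    if k < 3:
        raise ValueError("polynomial scores require k >= 3")
    x = np.arange(1, k + 1, dtype=float)
    basis = np.vander(x, 3, increasing=True)  # 1, x, x^2
    q, _ = np.linalg.qr(basis)
    linear, quadratic = q[:, 1], q[:, 2]
    if linear[-1] < 0:
        linear = -linear
    if quadratic[0] < 0:
        quadratic = -quadratic
    return linear, quadratic


def caf_summarize(
    trials: pd.DataFrame,
    k: int = 5,
    cell: tuple[str, ...] = DEFAULT_CELL,
    rt_col: str = "rt",
    onset_col: str = "onset_ms",
) -> pd.DataFrame:
    """Per-bin accuracy, mean RT and mean EMG onset, with polynomial scores.

    Expects a ``quantile`` column (see :func:`bin_quantiles`); adds it when
    absent.  Mean onset averages the trials with a detected onset only (used
    for horizontal placement when plotting CAFs).
    """
    if "quantile" not in trials.columns:
        trials = bin_quantiles(trials, k=k, cell=cell, rt_col=rt_col)
    lin, quad = polynomial_scores(k)
    rows = []
    for key, g in trials.groupby(list(cell) + ["quantile"], observed=True):
        *cell_vals, q = key
        row = dict(zip(cell, cell_vals))
        row["quantile"] = int(q)
        row["n_trials"] = len(g)
        row["accuracy"] = float(g["correct"].mean())
        row["mean_rt"] = float(g[rt_col].mean())
        onsets = g[onset_col].dropna() if onset_col in g.columns else pd.Series(dtype=float)
        row["mean_onset"] = float(onsets.mean()) if len(onsets) else np.nan
        row["quantile_linear"] = float(lin[int(q) - 1])
        row["quantile_quadratic"] = float(quad[int(q) - 1])
        rows.append(row)
    return pd.DataFrame(rows).sort_values(list(cell) + ["quantile"]).reset_index(drop=True)


def add_polynomial_covariates(trials: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Attach per-trial quantile_linear/quantile_quadratic covariates for the
    CAF mixed model (requires a ``quantile`` column)."""
    lin, quad = polynomial_scores(k)
    out = trials.copy()
    q = out["quantile"].to_numpy(dtype=int)
    if q.min() < 1 or q.max() > k:
        raise ValueError("quantile assignments outside 1..k")
    out["quantile_linear"] = lin[q - 1]
    out["quantile_quadratic"] = quad[q - 1]
    return out


def plot_caf(caf_table: pd.DataFrame, path, x_col: str = "mean_onset"):
    """Accuracy vs mean onset (or RT), one panel per bias block."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    blocks = caf_table["block"].unique()
    fig, axes = plt.subplots(1, len(blocks), figsize=(4 * len(blocks), 3.2),
                             sharey=True, squeeze=False)
    for ax, block in zip(axes[0], blocks):
        sub = caf_table[caf_table["block"] == block]
        for lex, g in sub.groupby("lexicality"):
            mean = g.groupby("quantile")[[x_col, "accuracy"]].mean()
            ax.plot(mean[x_col], mean["accuracy"], marker="o", label=lex)
        ax.set_title(block)
        ax.set_xlabel(f"{x_col} (ms)")
        ax.set_ylim(0, 1.02)
    axes[0][0].set_ylabel("proportion correct")
    axes[0][-1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
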