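"""Optional rendering of diagnostic series to image files.

The analysis itself is headless: every plot here is a direct rendering of
the numeric series in a :class:`~phenomm.diagnostics.DiagnosticBundle`, so
pipelines that only need the data never import matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import DiagnosticBundle  # noqa: E402


def render_diagnostics(bundle: DiagnosticBundle, out_dir, prefix: str = "",
                       fmt: str = "svg") -> list[Path]:
    """Write one image per populated diagnostic series; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(fig, name):
        path = out_dir / f"{prefix}{name}.{fmt}"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    def _qq(series, title, name):
        theo, samp = series
        if theo.size == 0:
            return
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(theo, samp, s=12)
        lim = [min(theo.min(), samp.min()), max(theo.max(), samp.max())]
        ax.plot(lim, lim, color="grey", lw=0.8)
        ax.set_xlabel("theoretical quantiles")
        ax.set_ylabel("sample quantiles")
        ax.set_title(title)
        _save(fig, name)

    _qq(bundle.qq_batch_means, "Normal Q-Q: batch means", "qq_batch_means")
    _qq(bundle.qq_blups, "Normal Q-Q: batch BLUPs", "qq_blups")
    for g, series in bundle.qq_residuals_per_genotype.items():
        _qq(series, f"Normal Q-Q: conditional residuals ({g})",
            f"qq_residuals_{g}")

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, (fitted, resid) in bundle.residual_vs_fitted_per_genotype.items():
        ax.scatter(fitted, resid, s=12, label=g, alpha=0.7)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("fitted (incl. batch BLUP)")
    ax.set_ylabel("conditional residual")
    ax.legend()
    _save(fig, "residual_vs_fitted")

    if bundle.weight_vs_trait is not None:
        w, y = bundle.weight_vs_trait
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(w, y, s=12)
        ax.set_xlabel("body weight (g)")
        ax.set_ylabel("trait value")
        _save(fig, "weight_vs_trait")

    return written
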