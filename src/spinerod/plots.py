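"""Optional overlay figures (initial vs deformed rods, axial projections).

Requires matplotlib; imported lazily so the core pipeline stays free of a
plotting dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_overlay_figures(report, out_dir: str | Path) -> None:
    """One 4-panel overlay (sagittal/frontal/axial/3D) per model, plus a
    superimposed axial projection of all normalized deformation fields."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, m in report.models.items():
        fig = plt.figure(figsize=(10, 8))
        views = [("sagittal (Y-Z)", 1, 2), ("frontal (X-Z)", 0, 2),
                 ("axial (X-Y)", 0, 1)]
        for i, (title, a, b) in enumerate(views, start=1):
            ax = fig.add_subplot(2, 2, i)
            ax.plot(m.initial[:, a], m.initial[:, b], "k.-", label="initial")
            ax.plot(m.deformed[:, a], m.deformed[:, b], "b.-", label="deformed")
            ax.set_title(f"{name} {title}")
            ax.axis("equal")
            if i == 1:
                ax.legend(fontsize=8)
        ax3 = fig.add_subplot(2, 2, 4, projection="3d")
        ax3.plot(*m.initial.T, "k.-")
        ax3.plot(*m.deformed.T, "b.-")
        ax3.set_title("3D")
        fig.tight_layout()
        fig.savefig(out / f"overlay_{name}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 6))
    for name, m in report.models.items():
        ax.plot(m.normalized_deformation[:, 0], m.normalized_deformation[:, 1],
                ".-", label=name)
    ax.set_xlabel("normalized u_X")
    ax.set_ylabel("normalized u_Y")
    ax.set_title("axial projection of normalized deformation")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "axial_deformations.png", dpi=120)
    plt.close(fig)
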