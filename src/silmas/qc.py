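"""Quality-control artifacts: ECR tables and before/after column profiles."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_ecr_table", "column_profile_plot"]


def write_ecr_table(rows: list[tuple[int, float]], path) -> None:
    """Write a per-plane energy-change-ratio table as CSV."""
    with open(path, "w") as fh:
        fh.write("plane,ecr\n")
        for plane, ecr in rows:
            fh.write(f"{plane},{ecr}\n")


def column_profile_plot(original: np.ndarray, filtered: np.ndarray, path) -> None:
    """Plot column-mean profiles before and after destriping."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(np.asarray(original, dtype=float).mean(axis=0), label="original", lw=0.8)
    ax.plot(np.asarray(filtered, dtype=float).mean(axis=0), label="filtered", lw=0.8)
    ax.set_xlabel("X (propagation axis, px)")
    ax.set_ylabel("column mean intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
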