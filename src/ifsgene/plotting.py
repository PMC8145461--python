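"""Optional matplotlib renderings of trajectories and attractor samples."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .switching import Trajectory  # noqa: E402

__all__ = ["plot_trajectory", "plot_cloud"]


def plot_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Molecule levels and gene state against physical time."""
    path = Path(path)
    fig, (ax_mol, ax_gene) = plt.subplots(
        2, 1, sharex=True, figsize=(8, 5), height_ratios=[3, 1]
    )
    for k, label in enumerate(("pre-mRNA", "mRNA", "protein")):
        ax_mol.plot(traj.times, traj.states[:, k], label=label, lw=0.9)
    ax_mol.set_ylabel("concentration")
    ax_mol.legend(loc="upper right", fontsize=8)
    ax_gene.step(traj.times, traj.gene, where="post", color="k", lw=0.8)
    ax_gene.set_yticks([0, 1])
    ax_gene.set_ylabel("gene")
    ax_gene.set_xlabel("time")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_cloud(points, path: str | Path, color=None, title: str | None = None) -> Path:
    """3-D scatter of a point cloud."""
    path = Path(path)
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(points[:, 0], points[:, 1], points[:, 2], s=0.5, c=color, alpha=0.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
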