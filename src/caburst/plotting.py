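"""Optional matplotlib rendering of sweep and bifurcation results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import BifurcationBranch, SweepResult  # noqa: E402


def plot_sweep(res: SweepResult, path: str) -> None:
    """Heat map(s) of NSPB: map side, plus network side when present."""
    panels = 1 if res.nspb_continuous is None else 2
    fig, axes = plt.subplots(1, panels, figsize=(5 * panels, 4), squeeze=False)
    mats = [("discrete map", res.nspb_map)]
    if res.nspb_continuous is not None:
        mats.append(("network", res.nspb_continuous))
    for ax, (title, mat) in zip(axes[0], mats):
        im = ax.imshow(mat, origin="lower", aspect="auto",
                       extent=(res.axis2_values[0], res.axis2_values[-1],
                               res.axis1_values[0], res.axis1_values[-1]))
        ax.set_xlabel(res.axis2_name)
        ax.set_ylabel(res.axis1_name)
        ax.set_title(f"NSPB ({title})")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_branches(branch: BifurcationBranch, path: str) -> None:
    """Step plot of the stable-NSPB branches along the scanned parameter."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(branch.values, branch.nspb_map, where="mid", label="discrete map")
    if branch.nspb_continuous is not None:
        ax.step(branch.values, branch.nspb_continuous, where="mid",
                label="network", linestyle="--")
    ax.set_xlabel(branch.param)
    ax.set_ylabel("stable NSPB")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
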