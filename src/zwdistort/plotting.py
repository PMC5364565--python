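"""Plot helpers: per-individual haplotype bars and model trajectories."""

from __future__ import annotations

import numpy as np

from .genotypes import MISSING

__all__ = ["plot_haplotype_bars", "plot_trajectories"]


def plot_haplotype_bars(phase_results, sex=None, ax=None, title=None):
    """Render phased inheritance states, one horizontal line per offspring.

    Colors: haplotype H1 steel blue, H2 orange, missing gray.  When ``sex``
    is given, offspring are sorted females first and a separator line is
    drawn.  Returns the matplotlib Axes.
    """
    import matplotlib.colors as mcolors
    import matplotlib.pyplot as plt

    states = phase_results.states
    if sex is not None:
        order = sex.reindex(states.index).map({"F": 0, "M": 1, "U": 2}).sort_values(
            kind="stable").index
        states = states.loc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2.0, 0.02 * len(states))))
    cmap = mcolors.ListedColormap(["#bdbdbd", "#4878a8", "#e08214"])
    img = states.to_numpy().astype(int) + 1  # missing -> 0
    ax.imshow(img, aspect="auto", cmap=cmap, interpolation="nearest", vmin=0, vmax=2)
    if sex is not None:
        n_f = int((sex.reindex(states.index) == "F").sum())
        ax.axhline(n_f - 0.5, color="black", lw=1)
    ax.set_xlabel("marker (map order)")
    ax.set_ylabel("offspring")
    if title:
        ax.set_title(title)
    return ax


def plot_trajectories(trajectories, ax=None, show_female_fraction=False):
    """Plot combined Z allele-frequency trajectories of one or more runs.

    ``trajectories`` is a mapping of curve label to Trajectory (a single
    Trajectory is accepted).  For each run the summed frequency of
    lethal/incompatible alleles is drawn (for overdominance every allele is
    incompatible, so the sum is 1 and per-allele curves are drawn instead).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    if not isinstance(trajectories, dict):
        trajectories = {"model": trajectories}
    for name, traj in trajectories.items():
        t = np.arange(len(traj))
        if traj.spec.model == "pseudooverdominance":
            lethal = np.array([
                sum(f for lab, f in zip(s.alleles, s.combined_Z_frequencies)
                    if set(lab) != {"0"})
                for s in traj.states
            ])
            ax.plot(t, lethal, label=f"{name} (lethal haplotypes)")
        else:
            for lab in traj.states[0].alleles:
                ax.plot(t, traj.combined_frequency(lab), alpha=0.7,
                        label=f"{name} {lab}" if len(traj.states[0].alleles) <= 4 else None)
        if show_female_fraction:
            ax.plot(t, traj.female_fractions(), ls="--", label=f"{name} female fraction")
    ax.set_xlabel("generation t")
    ax.set_ylabel("combined Z frequency")
    ax.set_ylim(0, 1)
    handles, _ = ax.get_legend_handles_labels()
    if handles:
        ax.legend(fontsize=8)
    return ax
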