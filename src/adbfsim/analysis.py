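"""Structural and diagnostic analyses: RDF/IRDF, QM-atom-count traces and
the buffer-size force-convergence scan.

The RDF here is centred on a designated molecule (the centre of the
dynamical QM region), not bulk-averaged: the structure around the QM
centre is exactly the quantity the adaptive machinery is supposed to
preserve.  The cumulative neighbour count is obtained by direct counting
per frame rather than by integrating g(r), which avoids quadrature noise
in sparse bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import minimum_image_displacement
from .forcefields import CompositeQMMM, WaterForceField
from .regions import RegionLabels, RegionSpec, partition

__all__ = ["RDFResult", "ForceScanResult", "rdf", "qm_count_trace",
           "buffer_convergence_scan", "plot_rdf"]


@dataclass
class RDFResult:
    r_bins: np.ndarray      # bin centres, A
    g: np.ndarray           # normalized pair density
    N_cum: np.ndarray       # mean cumulative neighbour count at bin upper edges
    frames_used: int

    def n_within(self, r: float) -> float:
        """Mean neighbour count within r (interpolated on the direct count)."""
        edges = self.r_bins + 0.5 * (self.r_bins[1] - self.r_bins[0])
        return float(np.interp(r, edges, self.N_cum))


def rdf(frames, center_index: int, partner_indices, r_max: float, dr: float) -> RDFResult:
    """Time-averaged radial distribution around one centre atom.

    ``frames`` is an iterable of SystemState (or (step, state, labels)
    tuples).  ``partner_indices`` may be a fixed index array or a callable
    state -> indices.  Normalization uses the ideal-gas shell density of
    the partner species in the cell volume.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    nbins = int(round(r_max / dr))
    counts = np.zeros(nbins)
    cum = np.zeros(nbins)
    n_frames = 0
    rho_sum = 0.0
    for fr in frames:
        state = fr[1] if isinstance(fr, tuple) else fr
        if np.any(state.pbc) and r_max > 0.5 * min(state.cell[state.pbc]) + 1e-9:
            raise ValueError("r_max exceeds half the smallest periodic cell edge")
        partners = np.asarray(partner_indices(state) if callable(partner_indices)
                              else partner_indices)
        partners = partners[partners != center_index]
        d = minimum_image_displacement(
            state.positions[partners] - state.positions[center_index],
            state.cell, state.pbc)
        r = np.linalg.norm(d, axis=-1)
        h, _ = np.histogram(r, bins=nbins, range=(0.0, r_max))
        counts += h
        cum += np.cumsum(h)
        vol = float(np.prod(state.cell))
        rho_sum += len(partners) / vol
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames")
    edges = np.linspace(0.0, r_max, nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = rho_sum / n_frames
    g = counts / n_frames / (shell * rho)
    return RDFResult(r_bins=centers, g=g, N_cum=cum / n_frames, frames_used=n_frames)


def qm_count_trace(frames, spec: RegionSpec) -> dict:
    """Extended-QM size and membership-switch statistics over a trajectory.

    Re-labels every stored frame sequentially under ``spec`` (hysteresis
    carries across frames), so a saved run can be re-analysed with
    modified radii.  A switch event is one molecule (or atom, when
    whole_molecules is off) changing its extended-QM membership between
    consecutive frames.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty trajectory")
    first = frames[0][1] if isinstance(frames[0], tuple) else frames[0]
    labels = RegionLabels.initial(first.n_atoms, spec)
    counts = []
    switches = 0
    prev_member = None
    for fr in frames:
        state = fr[1] if isinstance(fr, tuple) else fr
        labels = partition(state, spec, labels)
        counts.append(labels.counts()["n_extended"])
        in_ext = labels.label <= 2  # CORE/DYN_QM/BUFFER
        if spec.whole_molecules:
            mids = np.unique(state.molecule_id)
            member = np.array([in_ext[state.molecule_id == m].any() for m in mids])
        else:
            member = in_ext
        if prev_member is not None:
            switches += int(np.sum(member != prev_member))
        prev_member = member
    return {"n_extended": np.asarray(counts), "switch_events": switches}


@dataclass
class ForceScanResult:
    r_buffer: np.ndarray
    mean_error: np.ndarray   # per radius, averaged over configs and tagged atoms
    max_error: np.ndarray    # per radius, max over configs and tagged atoms
    reference_radius: float


def buffer_convergence_scan(states, tagged_atoms, r_buffer_grid, r_reference: float,
                            A: WaterForceField, B: WaterForceField,
                            spec: RegionSpec) -> ForceScanResult:
    """Force error on tagged dynamical-QM atoms vs. buffer radius.

    For each configuration the dynamical QM region is built from ``spec``
    (fresh, no hysteresis memory); the extended QM set is then enlarged by
    a non-hysteretic buffer of each radius in the grid and compared with
    the evaluation at ``r_reference``.
    """
    r_buffer_grid = np.asarray(sorted(r_buffer_grid), dtype=float)
    if r_reference < r_buffer_grid.max():
        raise ValueError("reference radius must not be smaller than the scan grid")
    tagged_atoms = np.asarray(tagged_atoms)
    comp = CompositeQMMM(A, B)
    errs = np.zeros((len(states), len(r_buffer_grid), len(tagged_atoms)))
    radii = np.append(r_buffer_grid, r_reference)
    for s_i, state in enumerate(states):
        labels = partition(state, spec, RegionLabels.initial(state.n_atoms, spec))
        dyn = labels.dyn_qm
        if not np.all(np.isin(tagged_atoms, dyn)):
            raise ValueError("tagged atom outside the dynamical QM region")
        forces = []
        for rb in radii:
            buf_spec = RegionSpec(fixed_core=tuple(spec.fixed_core),
                                  fixed_qm=tuple(spec.fixed_qm),
                                  r_core=spec.r_core, r_qm=spec.r_qm,
                                  r_buffer=(rb, rb),
                                  species_filter=spec.species_filter,
                                  whole_molecules=spec.whole_molecules,
                                  seed_is_only_fixed_core=spec.seed_is_only_fixed_core)
            lab = partition(state, buf_spec, RegionLabels.initial(state.n_atoms, buf_spec))
            ext = frozenset(lab.extended_qm.tolist())
            forces.append(comp.evaluate(state, ext).forces[tagged_atoms])
        ref = forces[-1]
        for r_i in range(len(r_buffer_grid)):
            errs[s_i, r_i] = np.linalg.norm(forces[r_i] - ref, axis=-1)
    return ForceScanResult(r_buffer=r_buffer_grid,
                           mean_error=errs.mean(axis=(0, 2)),
                           max_error=errs.max(axis=(0, 2)),
                           reference_radius=float(r_reference))


def plot_rdf(result: RDFResult, path, label: str | None = None) -> None:
    """Save g(r) and the cumulative neighbour count on twin panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(5, 4.5))
    ax1.plot(result.r_bins, result.g, label=label)
    ax1.set_ylabel("g(r)")
    if label:
        ax1.legend(frameon=False)
    ax2.plot(result.r_bins, result.N_cum)
    ax2.set_xlabel("r (A)")
    ax2.set_ylabel("N(<r)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
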