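"""Cross-PD compilation: CM identity and sense, occupancy maps, energies.

Eigendecomposition polarity is arbitrary per projection direction, so each
PD's CM labels and traversal directions (senses) must be reconciled before
its per-image bin indices can be intersected into one n-dimensional
occupancy map.  Boltzmann statistics then convert occupancies into a
relative free-energy landscape, Delta G = -kT ln(n / n_max).

Per-state image stacks plus alignment tables (orientation, defocus, pixel
size) are exported for external 3D reconstruction; a Fourier shell
correlation utility compares reconstructed maps against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


@dataclass
class PDResult:
    """Per-PD partitioning output: one bin index per image per local CM."""

    pd_id: int
    bins: dict[int, np.ndarray]          # local cm -> bin_of_image
    r2: dict[int, float]                 # local cm -> final subspace fit R^2
    B: int
    meta: "object | None" = None         # ImageMeta table (ground truth, alignment)
    occupancies: dict[int, np.ndarray] = field(default_factory=dict)
    movies: dict[int, "object"] = field(default_factory=dict)


@dataclass
class SenseMap:
    """(pd_id, local cm) -> (global CM label, sense in {+1, -1})."""

    assignments: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    ambiguous: set[tuple[int, int]] = field(default_factory=set)

    def corrected_bins(self, result: PDResult, global_cm: int) -> np.ndarray | None:
        for local, (g, sense) in self.assignments.items():
            if local[0] == result.pd_id and g == global_cm:
                b = result.bins[local[1]]
                return (result.B - 1 - b) if sense < 0 else b
        return None


@dataclass
class OccupancyMapND:
    counts: np.ndarray
    contributing_pds: list[int]
    gate: float

    @property
    def n(self) -> int:
        return self.counts.ndim


@dataclass
class EnergyLandscape:
    delta_g: np.ndarray          # masked (NaN) where counts == 0, in k_B T
    mask: np.ndarray
    reference_bin: tuple[int, ...]
    kT: float = 1.0


def align_senses(results: list[PDResult], mode: str = "ground_truth",
                 r2_min: float = 0.7) -> SenseMap:
    """Match each PD's local CMs to global CM labels and fix their senses.

    ground_truth (synthetic data): each local CM is labeled by the true
    state coordinate with maximal |Spearman correlation| to its bin index;
    the sense is the correlation's sign.

    reference_pd: the first PD passing the R^2 gate defines the global
    labels; other PDs are matched by the |correlation| of their bin
    occupancy profiles against the reference (forward and reversed; the
    better orientation sets the sense).  Near-ties (within 0.05) are
    flagged for review.
    """
    sm = SenseMap()
    if not results:
        raise ValueError("no PD results given")

    if mode == "ground_truth":
        for res in results:
            if res.meta is None:
                raise ValueError(f"PD {res.pd_id}: ground-truth mode needs meta")
            state_cols = [c for c in res.meta.columns if c.startswith("state_")]
            truth = res.meta[state_cols].to_numpy()
            for local, b in res.bins.items():
                rhos = []
                for g in range(truth.shape[1]):
                    rho = spearmanr(b, truth[:, g]).statistic
                    rhos.append(0.0 if np.isnan(rho) else rho)
                order = np.argsort([-abs(r) for r in rhos])
                gbest = int(order[0])
                if len(rhos) > 1 and abs(abs(rhos[gbest]) - abs(rhos[int(order[1])])) < 0.05:
                    sm.ambiguous.add((res.pd_id, local))
                sm.assignments[(res.pd_id, local)] = (
                    gbest + 1, 1 if rhos[gbest] >= 0 else -1)
        return sm

    if mode == "reference_pd":
        gated = [r for r in results
                 if r.r2 and all(v >= r2_min for v in r.r2.values())]
        if not gated:
            raise ValueError("no PD passes the R^2 gate to serve as reference")
        ref = gated[0]
        profiles = {}
        for local, b in ref.bins.items():
            sm.assignments[(ref.pd_id, local)] = (local, 1)
            profiles[local] = np.bincount(b, minlength=ref.B).astype(float)
        for res in results:
            if res.pd_id == ref.pd_id:
                continue
            for local, b in res.bins.items():
                prof = np.bincount(b, minlength=res.B).astype(float)
                scores = {}
                for g, ref_prof in profiles.items():
                    fwd = abs(np.corrcoef(prof, ref_prof)[0, 1])
                    rev = abs(np.corrcoef(prof[::-1], ref_prof)[0, 1])
                    scores[g] = (max(fwd, rev), 1 if fwd >= rev else -1)
                ranked = sorted(scores.items(), key=lambda kv: -kv[1][0])
                gbest, (best, sense) = ranked[0]
                if len(ranked) > 1 and best - ranked[1][1][0] < 0.05:
                    sm.ambiguous.add((res.pd_id, local))
                sm.assignments[(res.pd_id, local)] = (gbest, sense)
        return sm

    raise ValueError(f"unknown mode {mode!r}")


def intersect_indices(results: list[PDResult], sense_map: SenseMap,
                      n: int, r2_min: float = 0.7,
                      exclude_ambiguous: bool = True) -> OccupancyMapND:
    """Intersect per-image bin indices across CMs into an n-D occupancy map.

    For each gated PD, every image carries one sense-corrected bin index per
    global CM; the image increments the count of its (b_1, ..., b_n) cell.
    A PD missing a CM, with any CM subspace below the R^2 gate, or flagged
    by the sense matcher as ambiguous (its subspace mixes two motions) is
    excluded with a log entry.  n = 1 reduces to plain per-bin occupancy.
    """
    if not results:
        raise ValueError("no PD results")
    B = results[0].B
    counts = np.zeros((B,) * n, dtype=np.int64)
    contributing = []
    for res in results:
        if res.r2 and any(v < r2_min for v in res.r2.values()) or len(res.r2) < n:
            logger.info("PD %d excluded by R^2 gate %s", res.pd_id, res.r2)
            continue
        if exclude_ambiguous and any(pd == res.pd_id
                                     for pd, _ in sense_map.ambiguous):
            logger.info("PD %d excluded: ambiguous CM identity", res.pd_id)
            continue
        per_cm = []
        for g in range(1, n + 1):
            b = sense_map.corrected_bins(res, g)
            if b is None:
                per_cm = None
                break
            per_cm.append(b)
        if per_cm is None:
            logger.info("PD %d missing a CM assignment: excluded", res.pd_id)
            continue
        np.add.at(counts, tuple(per_cm), 1)
        contributing.append(res.pd_id)
    return OccupancyMapND(counts=counts, contributing_pds=contributing, gate=r2_min)


def occupancy_to_energy(occ: OccupancyMapND, kT: float = 1.0) -> EnergyLandscape:
    """Delta G = -kT ln(counts / max counts); empty cells are masked."""
    counts = occ.counts
    if counts.max() <= 0:
        raise ValueError("all-zero occupancy map")
    mask = counts == 0
    dg = np.full(counts.shape, np.nan)
    nz = ~mask
    dg[nz] = -kT * np.log(counts[nz] / counts.max())
    ref = np.unravel_index(int(counts.argmax()), counts.shape)
    return EnergyLandscape(delta_g=dg, mask=mask, reference_bin=ref, kT=kT)


# --------------------------------------------------------------------------
# per-state export
# --------------------------------------------------------------------------

@dataclass
class StateStackManifest:
    states: dict[tuple[int, ...], dict]   # cell -> {image_ids, stack, table}


def export_state_stacks(results: list[PDResult], sense_map: SenseMap,
                        stacks: dict[int, "object"], selection,
                        out_dir, n: int, r2_min: float = 0.7) -> StateStackManifest:
    """Write one MRCS stack + STAR alignment table per selected state cell.

    All images of gated PDs falling in a cell are pooled; the alignment
    table carries the orientation quaternion, defocus and pixel size needed
    by an external reconstruction package.  Empty cells are skipped with a
    warning.
    """
    from . import mrc, star
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = StateStackManifest(states={})
    for cell in selection:
        cell = tuple(int(c) for c in cell)
        imgs, rows = [], []
        for res in results:
            if res.r2 and any(v < r2_min for v in res.r2.values()):
                continue
            per_cm = [sense_map.corrected_bins(res, g) for g in range(1, n + 1)]
            if any(b is None for b in per_cm):
                continue
            sel = np.ones(len(per_cm[0]), dtype=bool)
            for b, c in zip(per_cm, cell):
                sel &= b == c
            if not sel.any():
                continue
            stack = stacks[res.pd_id]
            imgs.append(stack.images[sel])
            rows.append(res.meta.loc[sel])
        if not imgs:
            logger.warning("state cell %s is empty: skipped", cell)
            continue
        import pandas as pd
        images = np.concatenate(imgs)
        table = pd.concat(rows, ignore_index=True)
        tag = "_".join(f"{c:02d}" for c in cell)
        stack_path = out / f"state_{tag}.mrcs"
        table_path = out / f"state_{tag}.star"
        mrc.write_mrcs(images, stacks[results[0].pd_id].pixel_size_A, stack_path)
        star.write_star(table, table_path)
        manifest.states[cell] = {
            "image_ids": table["image_id"].tolist(),
            "stack": str(stack_path),
            "table": str(table_path),
        }
    return manifest


# --------------------------------------------------------------------------
# Fourier shell correlation
# --------------------------------------------------------------------------

def fsc(vol_a: np.ndarray, vol_b: np.ndarray, pixel_size: float = 1.0):
    """Per-shell normalized cross-correlation of two cubic maps.

    Returns (spatial_frequency [1/unit], fsc values), shells of unit voxel
    width in Fourier space up to Nyquist.
    """
    vol_a, vol_b = np.asarray(vol_a), np.asarray(vol_b)
    if vol_a.shape != vol_b.shape or len(set(vol_a.shape)) != 1:
        raise ValueError(f"volumes must be cubic with equal shapes, got "
                         f"{vol_a.shape} vs {vol_b.shape}")
    P = vol_a.shape[0]
    Fa, Fb = np.fft.fftn(vol_a), np.fft.fftn(vol_b)
    k = np.fft.fftfreq(P) * P
    kr = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2)
    shells = np.clip(np.round(kr).astype(int), 0, P // 2)
    n_shell = P // 2 + 1
    num = np.bincount(shells.ravel(), (Fa * np.conj(Fb)).real.ravel(), n_shell)
    pa = np.bincount(shells.ravel(), np.abs(Fa.ravel()) ** 2, n_shell)
    pb = np.bincount(shells.ravel(), np.abs(Fb.ravel()) ** 2, n_shell)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = num / np.sqrt(pa * pb)
    curve = np.nan_to_num(curve, nan=0.0)
    freq = np.arange(n_shell) / (P * pixel_size)
    return freq, curve


def resolution_at(freq: np.ndarray, curve: np.ndarray,
                  threshold: float = 0.143) -> float:
    """Resolution = 1 / frequency at the first crossing below threshold
    (linear interpolation between shells); Nyquist if never crossed."""
    below = np.nonzero(curve[1:] < threshold)[0]
    if below.size == 0:
        return float(1.0 / freq[-1])
    i = below[0] + 1
    f0, f1 = freq[i - 1], freq[i]
    c0, c1 = curve[i - 1], curve[i]
    f_cross = f0 if c0 == c1 else f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
    return float(1.0 / f_cross)
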