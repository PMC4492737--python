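"""The clustering metric: inter-atomic distance fluctuations.

Two variants share one container:

* **ensemble mode** — ``D_mn`` is the population standard deviation of the
  per-frame Euclidean distance ``d_mn`` over the trajectory,
  ``D_mn = <Δd_mn²>^{1/2}``, and ``M_mn = <d_mn>`` is its time average.
* **pair mode** — for two static structures, ``D_mn = |d_mn,1 − d_mn,2|``
  and ``M_mn`` is the mean of the two distances.

Both are superposition-free: no fitting, imaging or alignment is needed,
and the result is invariant under arbitrary per-frame rigid motions.

Population (divide-by-n) variance is used: the metric is an ensemble
average, and it fixes the exact two-frame identity
``D_ensemble = D_pair / 2``. For a two-frame ensemble the standard
deviation is evaluated in its exact half-range form ``|d₁−d₂|/2``; the
general path is a single streaming pass using the first frame's distances
as an offset, which keeps the accumulation free of catastrophic
cancellation (fluctuations are small against mean distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ComputationError, InputError
from .trajectory_io import Ensemble, Label, StructureFrame

__all__ = [
    "DistanceStatsMatrix",
    "distance_stats",
    "pair_difference_matrix",
    "save_stats",
    "load_stats",
]


@dataclass
class DistanceStatsMatrix:
    """Symmetric fluctuation matrix D plus mean-distance matrix M (Å)."""

    D: np.ndarray
    M: np.ndarray
    n_frames: int
    mode: str  # "ensemble" | "pair"
    labels: list[Label] = field(default_factory=list)

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=np.float64)
        self.M = np.asarray(self.M, dtype=np.float64)
        n = self.D.shape[0]
        if self.D.shape != (n, n) or self.M.shape != (n, n):
            raise InputError("D and M must be square and same shape")
        if self.mode not in ("ensemble", "pair"):
            raise InputError(f"unknown mode {self.mode!r}")

    @property
    def n_atoms(self) -> int:
        return self.D.shape[0]


def distance_stats(ensemble: Ensemble) -> DistanceStatsMatrix:
    """Per-pair distance fluctuation (std dev) and mean over the frames."""
    coords = ensemble.coords
    nf = coords.shape[0]
    if nf < 2:
        raise ComputationError(
            f"fluctuation analysis needs ≥ 2 frames, got {nf}"
        )
    if nf == 2:
        d1 = pdist(coords[0])
        d2 = pdist(coords[1])
        dvec = np.abs(d1 - d2) * 0.5  # exact 2-sample population std
        mvec = (d1 + d2) * 0.5
    else:
        d0 = pdist(coords[0])
        s1 = np.zeros_like(d0)
        s2 = np.zeros_like(d0)
        for f in range(nf):
            dev = pdist(coords[f]) - d0
            s1 += dev
            s2 += dev * dev
        mdev = s1 / nf
        var = s2 / nf - mdev * mdev
        np.maximum(var, 0.0, out=var)  # clamp cancellation residue
        dvec = np.sqrt(var)
        mvec = d0 + mdev
    return DistanceStatsMatrix(
        D=squareform(dvec),
        M=squareform(mvec),
        n_frames=nf,
        mode="ensemble",
        labels=list(ensemble.labels),
    )


def pair_difference_matrix(
    a: StructureFrame, b: StructureFrame
) -> DistanceStatsMatrix:
    """Distance-difference matrix between two structures of one protein."""
    if a.n_atoms != b.n_atoms:
        raise InputError(
            f"atom count mismatch: {a.n_atoms} vs {b.n_atoms}"
        )
    mism = [
        (la, lb)
        for la, lb in zip(a.labels, b.labels)
        if la.key != lb.key
    ]
    if mism:
        shown = ", ".join(f"{la} vs {lb}" for la, lb in mism[:5])
        raise InputError(f"label mismatch between structures: {shown}")
    d1 = pdist(a.coords)
    d2 = pdist(b.coords)
    dvec = np.abs(d1 - d2)
    if dvec.size and dvec.max() == 0.0:
        warnings.warn(
            "structures are identical: distance-difference matrix is zero "
            "and every tree node will score 0 Å",
            UserWarning,
            stacklevel=2,
        )
    return DistanceStatsMatrix(
        D=squareform(dvec),
        M=squareform((d1 + d2) * 0.5),
        n_frames=2,
        mode="pair",
        labels=list(a.labels),
    )


def save_stats(stats: DistanceStatsMatrix, path, binary: bool = False) -> None:
    """Dump D and M with a one-line header (text) or as an .npz (binary)."""
    if binary:
        np.savez_compressed(
            path,
            D=stats.D,
            M=stats.M,
            n_frames=stats.n_frames,
            mode=stats.mode,
            labels=np.array([list(l) for l in stats.labels], dtype=object),
        )
        return
    with open(path, "w") as fh:
        fh.write(
            f"# N={stats.n_atoms} mode={stats.mode} n_frames={stats.n_frames}\n"
        )
        np.savetxt(fh, stats.D, fmt="%.10g")
        np.savetxt(fh, stats.M, fmt="%.10g")


def load_stats(path) -> DistanceStatsMatrix:
    """Inverse of :func:`save_stats` (text form; labels are not stored)."""
    with open(path) as fh:
        header = fh.readline()
        try:
            kv = dict(tok.split("=") for tok in header.lstrip("# ").split())
            n = int(kv["N"])
            mode = kv["mode"]
            nf = int(kv["n_frames"])
        except (KeyError, ValueError) as exc:
            raise InputError(f"bad stats header in {path}") from exc
        data = np.loadtxt(fh)
    if data.shape != (2 * n, n):
        raise InputError(f"bad stats payload shape {data.shape} in {path}")
    labels = [Label("A", i + 1, "", "UNK") for i in range(n)]
    return DistanceStatsMatrix(
        D=data[:n], M=data[n:], n_frames=nf, mode=mode, labels=labels
    )
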