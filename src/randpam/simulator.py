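"""Stochastic realization of photon allocation over a microvillus population.

Per-microvillus hit counts are marginally Binomial(N_ph, 1/N_u) — Poisson in
the many-microvilli limit — but the physical input is a *fixed* photon count
per bin and every photon is absorbed, so realized hits must sum exactly to
the stimulus, bin by bin.  Independent Poisson draws per microvillus would
violate that (their sum is itself Poisson).  Two allocation schemes enforce
the constraint:

``multinomial``
    Each photon independently lands on a uniformly chosen microvillus; the
    per-bin total is conserved by construction and the marginal law is the
    exact binomial.  This is the default.

``compound_binomial``
    Occupancy-class realization: for x = x_n down to 1 draw round(N_u*P(x))
    distinct microvilli to absorb x photons each, where x_n is the largest x
    with N_u*P(x) > 1 (below one microvillus the class is dropped — the
    digitization limit).  Expected class sizes need not sum to N_ph, so a
    residual-correction step settles the difference with single-photon
    adjustments (see :func:`allocate_compound_binomial`).

Bins are independent: the same single-bin process is repeated along the
stimulus.  Allocations are sparse event tables (bin, microvillus, hits),
reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .photon_statistics import SamplingGeometry, expected_microvilli_with_x_hits
from .stimuli import LightStimulus

__all__ = [
    "PhotonAllocation",
    "HitSeries",
    "allocate_multinomial",
    "allocate_compound_binomial",
    "simulate",
    "reconstruct_stimulus",
    "hit_series",
    "empirical_multi_photon_fraction",
    "write_events",
    "read_events",
]


class AllocationInfeasibleError(RuntimeError):
    """Raised when a bin's photons cannot be placed under the scheme's rules."""


@dataclass
class PhotonAllocation:
    """Sparse per-bin assignment of photons to microvilli.

    ``bins``, ``microvilli`` and ``hits`` are parallel arrays; each row says
    that microvillus ``microvilli[i]`` absorbed ``hits[i]`` (>= 1) photons in
    bin ``bins[i]``.  Totals per bin equal the driving stimulus exactly.
    """

    n_bins: int
    geometry: SamplingGeometry
    bins: np.ndarray
    microvilli: np.ndarray
    hits: np.ndarray
    seed: int | None = None
    method: str = "multinomial"
    sampling_rate: float = 1000.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        self.microvilli = np.asarray(self.microvilli, dtype=np.int64)
        self.hits = np.asarray(self.hits, dtype=np.int64)
        if not (self.bins.shape == self.microvilli.shape == self.hits.shape):
            raise ValueError("bins, microvilli and hits must be parallel arrays")
        if self.hits.size and self.hits.min() < 1:
            raise ValueError("every stored event must carry at least one hit")

    @property
    def n_events(self) -> int:
        return int(self.hits.size)

    @property
    def total_photons(self) -> int:
        return int(self.hits.sum())

    def lambda_estimate(self) -> float:
        """Mean hits per microvillus per bin over the whole run."""
        return self.total_photons / (self.n_bins * self.geometry.n_microvilli)

    def multi_photon_fraction(self) -> float:
        """Realized fraction of hit microvilli that took >= 2 photons."""
        if self.n_events == 0:
            return 0.0
        return float(np.count_nonzero(self.hits >= 2) / self.n_events)

    def to_dense(self, max_cells: int = 50_000_000) -> np.ndarray:
        """(n_bins, N_u) hit-count matrix; refuses absurdly large grids."""
        n_u = self.geometry.n_microvilli
        if self.n_bins * n_u > max_cells:
            raise ValueError(
                f"dense export of {self.n_bins} x {n_u} exceeds max_cells={max_cells}"
            )
        dense = np.zeros((self.n_bins, n_u), dtype=np.int64)
        dense[self.bins, self.microvilli] = self.hits
        return dense


@dataclass
class HitSeries:
    """Per-bin hit counts experienced by one microvillus."""

    microvillus_id: int
    counts: np.ndarray


def allocate_multinomial(
    n_photons: int, geometry: SamplingGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute ``n_photons`` over the microvilli, one uniform draw each.

    Returns ``(microvillus_ids, hits)`` for the occupied microvilli.  The
    joint law of the hit vector is Multinomial(N_ph; 1/N_u, ..., 1/N_u),
    so each microvillus is marginally Binomial(N_ph, 1/N_u) and the total
    is conserved by construction.
    """
    if n_photons < 0:
        raise ValueError(f"n_photons must be non-negative, got {n_photons}")
    if n_photons == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    landing = rng.integers(0, geometry.n_microvilli, size=n_photons)
    ids, hits = np.unique(landing, return_counts=True)
    return ids.astype(np.int64), hits.astype(np.int64)


def _expected_class_sizes(
    n_photons: int, geometry: SamplingGeometry
) -> tuple[int, np.ndarray]:
    """x_n and round-half-away-from-zero class sizes n_x for x = 1..x_n."""
    lam = n_photons / geometry.n_microvilli
    x_cap = int(min(n_photons, math.ceil(lam + 12 * math.sqrt(lam + 1) + 20)))
    expected = np.array(
        [expected_microvilli_with_x_hits(n_photons, geometry, x) for x in range(1, x_cap + 1)]
    )
    above = np.nonzero(expected > 1.0)[0]
    if above.size == 0:
        return 0, np.empty(0, dtype=np.int64)
    x_n = int(above[-1] + 1)
    # round half away from zero; digitization floor of one microvillus per class
    sizes = np.floor(expected[:x_n] + 0.5).astype(np.int64)
    sizes = np.maximum(sizes, 1)
    return x_n, sizes


def allocate_compound_binomial(
    n_photons: int, geometry: SamplingGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Occupancy-class allocation with exact-total residual correction.

    For x = x_n down to 1, round(N_u*P(x)) distinct microvilli (distinct
    across classes too: one x value per microvillus per bin) each absorb x
    photons.  The drawn total can differ from ``n_photons``; the residual is
    settled by the smallest perturbation available in single-photon units:
    a positive residual adds 1-hit events on unoccupied microvilli, a
    negative one removes 1-hit events (decrementing >= 2-hit events only
    once the 1-hit pool is exhausted).  Returns ``(ids, hits, x_n)``.

    Raises
    ------
    AllocationInfeasibleError
        If the correction cannot reach ``n_photons`` (pathologically small
        microvillus populations).
    """
    if n_photons < 0:
        raise ValueError(f"n_photons must be non-negative, got {n_photons}")
    n_u = geometry.n_microvilli
    if n_photons == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 0

    x_n, sizes = _expected_class_sizes(n_photons, geometry)
    n_occupied = int(sizes.sum())
    if n_occupied > n_u:
        raise AllocationInfeasibleError(
            f"occupancy classes need {n_occupied} microvilli but only {n_u} exist"
        )
    chosen = rng.permutation(n_u)[:n_occupied].astype(np.int64)
    hits = np.repeat(np.arange(x_n, 0, -1, dtype=np.int64), sizes[::-1])
    ids = chosen

    residual = n_photons - int(hits.sum())
    if residual > 0:
        free = np.setdiff1d(np.arange(n_u, dtype=np.int64), ids, assume_unique=False)
        if residual > free.size:
            raise AllocationInfeasibleError(
                f"need {residual} extra single-photon hits but only {free.size} "
                f"unoccupied microvilli remain (N_u={n_u}, N_ph={n_photons})"
            )
        extra = rng.choice(free, size=residual, replace=False)
        ids = np.concatenate([ids, extra])
        hits = np.concatenate([hits, np.ones(residual, dtype=np.int64)])
    elif residual < 0:
        deficit = -residual
        order = rng.permutation(ids.size)
        ids, hits = ids[order], hits[order]
        singles = np.nonzero(hits == 1)[0]
        n_drop = min(deficit, singles.size)
        keep = np.ones(ids.size, dtype=bool)
        keep[singles[:n_drop]] = False
        deficit -= n_drop
        ids, hits = ids[keep], hits[keep]
        while deficit > 0:
            multis = np.nonzero(hits >= 2)[0]
            if multis.size == 0:
                raise AllocationInfeasibleError(
                    f"cannot remove {deficit} more photons: no events left to shrink"
                )
            take = multis[: deficit]
            hits[take] -= 1
            deficit -= take.size
            drop = np.nonzero(hits == 0)[0]
            if drop.size:
                keep = np.ones(ids.size, dtype=bool)
                keep[drop] = False
                ids, hits = ids[keep], hits[keep]

    order = np.argsort(ids)
    return ids[order], hits[order], x_n


def simulate(
    stimulus: LightStimulus,
    geometry: SamplingGeometry,
    seed: int | None = None,
    method: str = "multinomial",
) -> PhotonAllocation:
    """Allocate every bin of ``stimulus`` independently over the microvilli.

    Deterministic given (stimulus, geometry, seed, method).  The multinomial
    path is vectorized across bins; the compound-binomial path realizes one
    bin at a time.
    """
    counts = stimulus.counts
    if method not in ("multinomial", "compound_binomial"):
        raise ValueError(f"unknown allocation method: {method!r}")
    rng = np.random.default_rng(seed)
    n_bins = counts.size
    n_u = geometry.n_microvilli
    metadata: dict = {}

    if method == "multinomial":
        total = int(counts.sum())
        landing = rng.integers(0, n_u, size=total)
        bin_of_photon = np.repeat(np.arange(n_bins, dtype=np.int64), counts)
        key = bin_of_photon * n_u + landing
        uniq, hits = np.unique(key, return_counts=True)
        bins = uniq // n_u
        microvilli = uniq % n_u
    else:
        bin_list, id_list, hit_list = [], [], []
        x_n_max = 0
        for b in range(n_bins):
            try:
                ids, hits_b, x_n = allocate_compound_binomial(int(counts[b]), geometry, rng)
            except AllocationInfeasibleError as exc:
                raise AllocationInfeasibleError(f"bin {b}: {exc}") from exc
            x_n_max = max(x_n_max, x_n)
            bin_list.append(np.full(ids.size, b, dtype=np.int64))
            id_list.append(ids)
            hit_list.append(hits_b)
        bins = np.concatenate(bin_list) if bin_list else np.empty(0, dtype=np.int64)
        microvilli = np.concatenate(id_list) if id_list else np.empty(0, dtype=np.int64)
        hits = np.concatenate(hit_list) if hit_list else np.empty(0, dtype=np.int64)
        metadata["x_n_max"] = x_n_max
        metadata["residual_correction"] = "single_photon_adjustment"

    return PhotonAllocation(
        n_bins=n_bins,
        geometry=geometry,
        bins=bins,
        microvilli=microvilli,
        hits=hits,
        seed=seed,
        method=method,
        sampling_rate=stimulus.sampling_rate,
        metadata=metadata,
    )


def reconstruct_stimulus(allocation: PhotonAllocation) -> LightStimulus:
    """Sum hits per bin — recovers the driving stimulus exactly.

    Every photon is absorbed by exactly one microvillus, so adding all hits
    back up per bin must reproduce the input light pattern bin for bin.
    """
    counts = np.bincount(allocation.bins, weights=allocation.hits, minlength=allocation.n_bins)
    return LightStimulus(
        counts=counts.astype(np.int64),
        sampling_rate=allocation.sampling_rate,
        metadata={"reconstructed_from": allocation.method},
    )


def hit_series(allocation: PhotonAllocation, microvillus_id: int) -> HitSeries:
    """Dense per-bin hit counts for one microvillus."""
    if not 0 <= microvillus_id < allocation.geometry.n_microvilli:
        raise ValueError(
            f"microvillus_id {microvillus_id} outside [0, {allocation.geometry.n_microvilli})"
        )
    counts = np.zeros(allocation.n_bins, dtype=np.int64)
    mask = allocation.microvilli == microvillus_id
    counts[allocation.bins[mask]] = allocation.hits[mask]
    return HitSeries(microvillus_id=microvillus_id, counts=counts)


def empirical_multi_photon_fraction(
    n_photons: int,
    geometry: SamplingGeometry,
    n_bins: int,
    seed: int | None = None,
    chunk_cells: int = 20_000_000,
) -> tuple[float, float, int]:
    """Monte-Carlo multi-photon-hit fraction under multinomial allocation.

    Replays ``n_bins`` independent bins of ``n_photons`` photons and counts,
    per (bin, microvillus), how many occupied microvilli took >= 2 hits.
    Works in chunks of bins via offset bincount so runs of 1e8+ photons need
    neither the event list nor a per-bin Python loop.

    Returns ``(fraction, standard_error, n_hit_microvilli)`` where the SE is
    the binomial standard error over hit microvilli.
    """
    if n_photons < 0 or n_bins < 1:
        raise ValueError("n_photons must be >= 0 and n_bins >= 1")
    n_u = geometry.n_microvilli
    rng = np.random.default_rng(seed)
    bins_per_chunk = max(1, chunk_cells // n_u)
    n_hit = 0
    n_multi = 0
    done = 0
    while done < n_bins:
        chunk = min(bins_per_chunk, n_bins - done)
        landing = rng.integers(0, n_u, size=chunk * n_photons)
        offsets = np.repeat(np.arange(chunk, dtype=np.int64) * n_u, n_photons)
        per_unit = np.bincount(landing + offsets, minlength=chunk * n_u)
        n_hit += int(np.count_nonzero(per_unit))
        n_multi += int(np.count_nonzero(per_unit > 1))
        done += chunk
    if n_hit == 0:
        return 0.0, 0.0, 0
    frac = n_multi / n_hit
    se = math.sqrt(max(frac * (1.0 - frac), 1e-300) / n_hit)
    return frac, se, n_hit


def write_events(allocation: PhotonAllocation, path) -> None:
    """Write the event table to HDF5 (``.h5``/``.hdf5``) or CSV.

    HDF5 stores bin/microvillus/hits datasets with run metadata as root
    attributes; CSV writes the same three columns after ``#`` metadata lines.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("bin", data=allocation.bins)
            fh.create_dataset("microvillus", data=allocation.microvilli)
            fh.create_dataset("hits", data=allocation.hits)
            fh.attrs["n_bins"] = allocation.n_bins
            fh.attrs["n_microvilli"] = allocation.geometry.n_microvilli
            fh.attrs["bin_duration_ms"] = allocation.geometry.bin_duration_ms
            fh.attrs["sampling_rate_hz"] = allocation.sampling_rate
            fh.attrs["method"] = allocation.method
            if allocation.seed is not None:
                fh.attrs["seed"] = allocation.seed
    else:
        with open(path, "w") as fh:
            fh.write(f"# n_bins={allocation.n_bins}\n")
            fh.write(f"# n_microvilli={allocation.geometry.n_microvilli}\n")
            fh.write(f"# bin_duration_ms={allocation.geometry.bin_duration_ms:g}\n")
            fh.write(f"# sampling_rate_hz={allocation.sampling_rate:g}\n")
            fh.write(f"# method={allocation.method}\n")
            if allocation.seed is not None:
                fh.write(f"# seed={allocation.seed}\n")
            fh.write("bin,microvillus,hits\n")
            for b, m, h in zip(allocation.bins, allocation.microvilli, allocation.hits):
                fh.write(f"{b},{m},{h}\n")


def read_events(path) -> PhotonAllocation:
    """Read an event table written by :func:`write_events`."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            geometry = SamplingGeometry(
                n_microvilli=int(fh.attrs["n_microvilli"]),
                bin_duration_ms=float(fh.attrs.get("bin_duration_ms", 1.0)),
            )
            return PhotonAllocation(
                n_bins=int(fh.attrs["n_bins"]),
                geometry=geometry,
                bins=fh["bin"][:],
                microvilli=fh["microvillus"][:],
                hits=fh["hits"][:],
                seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
                method=str(fh.attrs.get("method", "multinomial")),
                sampling_rate=float(fh.attrs.get("sampling_rate_hz", 1000.0)),
            )
    meta: dict = {}
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for line in fh:
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                key, _, val = text.lstrip("#").strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if text.startswith("bin,"):
                continue
            b, m, h = text.split(",")
            rows.append((int(b), int(m), int(h)))
    geometry = SamplingGeometry(
        n_microvilli=int(meta["n_microvilli"]),
        bin_duration_ms=float(meta.get("bin_duration_ms", 1.0)),
    )
    arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
    return PhotonAllocation(
        n_bins=int(meta["n_bins"]),
        geometry=geometry,
        bins=arr[:, 0],
        microvilli=arr[:, 1],
        hits=arr[:, 2],
        seed=int(meta["seed"]) if "seed" in meta else None,
        method=meta.get("method", "multinomial"),
        sampling_rate=float(meta.get("sampling_rate_hz", 1000.0)),
    )
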