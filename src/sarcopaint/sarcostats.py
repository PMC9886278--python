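"""Aggregate statistics over per-sarcomere epitope measurements.

Epitope positions are pooled per-sarcomere across myofibrils and
experiments, unweighted; their uncertainty comes from a nonparametric
bootstrap (1000 replicates, each the size of the dataset, drawn with
replacement; the 95% interval is the 2.5/97.5% empirical quantile of the
replicate means, with linear interpolation between order statistics).
Dual-epitope ordering is the per-sarcomere count of strict inequalities;
ties count as not-closer.  Composite profiles are bin-wise sums of
per-Z-disc windows re-centred at their band-pair midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .bands import EpitopeMeasurement
from .errors import GridMismatchError, ValidationError
from .geometry import AxialProfile


@dataclass
class BootstrapResult:
    mean_nm: float
    ci_low_nm: float
    ci_high_nm: float
    n_replicates: int
    n_observations: int
    seed: int


@dataclass
class OrderingResult:
    """How often epitope A sits closer to the Z-disc than epitope B."""

    n_closer: int
    n_total: int
    mean_offset_nm: float
    n_ties: int = 0

    @property
    def fraction(self) -> float:
        return self.n_closer / self.n_total if self.n_total else float("nan")


@dataclass
class DistanceLengthFit:
    """Separation-vs-sarcomere-length regression."""

    lengths_nm: np.ndarray
    separations_nm: np.ndarray
    slope: float
    slope_se: float
    intercept: float


def known_labels(measurements: Iterable[EpitopeMeasurement]) -> list[str]:
    seen: list[str] = []
    for m in measurements:
        if m.epitope_label not in seen:
            seen.append(m.epitope_label)
    return seen


def half_distance_series(
    measurements: Sequence[EpitopeMeasurement], epitope_label: str
) -> np.ndarray:
    """All half-distances for one epitope, pooled unweighted, input order."""
    values = [m.half_distance_nm for m in measurements
              if m.epitope_label == epitope_label]
    if not values and measurements:
        labels = known_labels(measurements)
        if epitope_label not in labels:
            raise ValidationError(
                f"unknown epitope label '{epitope_label}'; known: {labels}")
    return np.asarray(values, dtype=float)


def bootstrap_mean(
    values: Sequence[float], n_replicates: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Bootstrap the mean of a dataset; deterministic given the seed."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("bootstrap_mean needs at least one value")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if values.size == 1:
        warnings.warn("bootstrap of a single value has a zero-width CI",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_replicates, values.size))
    replicate_means = values[idx].mean(axis=1)
    lo, hi = np.quantile(replicate_means, [0.025, 0.975])
    return BootstrapResult(
        mean_nm=float(values.mean()),
        ci_low_nm=float(lo),
        ci_high_nm=float(hi),
        n_replicates=n_replicates,
        n_observations=int(values.size),
        seed=seed,
    )


def ordering_fraction(
    measurements: Sequence[EpitopeMeasurement],
    epitope_a: str,
    epitope_b: str,
) -> OrderingResult:
    """Count Z-discs where A's half-distance is strictly below B's.

    Measurements are matched by (myofibril_id, zdisc_id); Z-discs lacking
    either epitope are ignored.  Ties count as not-closer.
    """
    by_key_a = {(m.myofibril_id, m.zdisc_id): m.half_distance_nm
                for m in measurements if m.epitope_label == epitope_a}
    by_key_b = {(m.myofibril_id, m.zdisc_id): m.half_distance_nm
                for m in measurements if m.epitope_label == epitope_b}
    common = sorted(set(by_key_a) & set(by_key_b))
    if not common:
        raise ValidationError(
            f"no Z-disc carries both '{epitope_a}' and '{epitope_b}'")
    a = np.array([by_key_a[k] for k in common])
    b = np.array([by_key_b[k] for k in common])
    n_ties = int(np.sum(a == b))
    if n_ties:
        warnings.warn(f"{n_ties} exact ties counted as not-closer",
                      stacklevel=2)
    return OrderingResult(
        n_closer=int(np.sum(a < b)),
        n_total=len(common),
        mean_offset_nm=float(np.mean(b - a)),
        n_ties=n_ties,
    )


def align_and_sum_profiles(
    profiles: Sequence[AxialProfile],
    reference_positions_nm: Sequence[float],
) -> AxialProfile:
    """Sum per-Z-disc windows after re-centring each at its reference.

    Every window is shifted so its reference (typically the band-pair
    midpoint) sits at 0; the shifted grids must coincide to within
    1e-6 nm, and counts are conserved bin-wise.
    """
    if len(profiles) == 0:
        raise ValidationError("no profiles to sum")
    if len(profiles) != len(reference_positions_nm):
        raise ValidationError("one reference position per profile required")
    ref_edges = profiles[0].bin_edges - reference_positions_nm[0]
    total = np.zeros_like(profiles[0].counts, dtype=float)
    for prof, center in zip(profiles, reference_positions_nm):
        edges = prof.bin_edges - center
        if edges.shape != ref_edges.shape or not np.allclose(
                edges, ref_edges, atol=1e-6):
            raise GridMismatchError("profiles are not on a common grid")
        total += prof.counts
    return AxialProfile(bin_edges=ref_edges, counts=total,
                        bin_size_nm=profiles[0].bin_size_nm)


def distance_vs_length(
    measurements: Sequence[EpitopeMeasurement],
    sarcomere_length_by_zdisc: Mapping[tuple[int, int], float],
    epitope_label: str | None = None,
) -> DistanceLengthFit:
    """Regress band separation on local sarcomere length.

    A slope consistent with zero means the epitope distance from the
    Z-disc does not scale with the (slightly variable) sarcomere length,
    which licenses pooling across sarcomeres.
    """
    pairs = [
        (sarcomere_length_by_zdisc[(m.myofibril_id, m.zdisc_id)],
         m.separation_nm)
        for m in measurements
        if (epitope_label is None or m.epitope_label == epitope_label)
        and (m.myofibril_id, m.zdisc_id) in sarcomere_length_by_zdisc
    ]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 (length, separation) pairs")
    lengths = np.array([p[0] for p in pairs])
    seps = np.array([p[1] for p in pairs])
    if np.ptp(lengths) == 0:
        raise ValidationError("degenerate sarcomere-length variance")
    fit = sps.linregress(lengths, seps)
    return DistanceLengthFit(
        lengths_nm=lengths,
        separations_nm=seps,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
    )
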