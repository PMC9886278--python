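"""Synthetic DNA-PAINT localization tables with known sarcomere geometry.

The generator emulates the *output* of a single-molecule reconstruction
of a stained flight-muscle myofibril: a 1-D lattice of Z-discs with a
~3.5 um, slightly jittered period; for each epitope a pair of bands at
± its offset from every Z-disc; per-localization noise at the 4-8 nm
precision the technique delivers; a uniform background along the axis;
and a contaminating multi-emitter population recognizable by inflated
(sx, sy) fit widths.  Blinking kinetics are not modelled at the frame
level — the analysis consumes localizations, so frames are bookkeeping.

Sarcomere-to-sarcomere biological variability of an epitope's position is
modelled by jittering the offset per (epitope, Z-disc), symmetrically on
both sides; its default (3.5 nm) reproduces the few-nm spread of
half-distances seen across real sarcomeres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .locio import DEFAULT_PIXEL_SIZE_NM, LocalizationTable, PickRegion

#: nominal single-emitter PSF fit width and its spread (camera pixels)
NOMINAL_PSF_WIDTH_PX = 1.0
PSF_WIDTH_SD_PX = 0.04
#: extra fit width of multi-emitter outliers, uniform in this range (px)
OUTLIER_SHIFT_PX = (0.3, 0.8)

AXIS_MARGIN_NM = 2000.0
SCENE_CENTER_PX = (400.0, 400.0)


@dataclass
class EpitopeSpec:
    """One labelled epitope: its half-distance from the Z-disc and spread."""

    label: str
    offset_nm: float
    band_sigma_nm: float = 12.0
    n_locs_per_band: int = 300
    channel_label: str = ""
    offset_sd_nm: float = 3.5

    def validate(self) -> None:
        if self.offset_nm <= 0:
            raise ValidationError("offset_nm must be positive")
        if self.band_sigma_nm < 0 or self.offset_sd_nm < 0:
            raise ValidationError("band_sigma_nm/offset_sd_nm must be >= 0")
        if self.n_locs_per_band < 1:
            raise ValidationError("n_locs_per_band must be >= 1")


def _default_epitopes() -> list[EpitopeSpec]:
    # titin-homolog N/C-terminal geometry: inner band ~50 nm, outer ~98 nm
    return [
        EpitopeSpec(label="sls_nterm", offset_nm=50.0),
        EpitopeSpec(label="sls_cterm", offset_nm=98.0),
    ]


@dataclass
class SimConfig:
    """Study conditions for one simulated myofibril."""

    n_sarcomeres: int = 30
    sarcomere_mean_nm: float = 3500.0
    sarcomere_sd_nm: float = 100.0
    epitopes: list[EpitopeSpec] = field(default_factory=_default_epitopes)
    loc_precision_nm: float = 5.0
    background_per_um: float = 30.0
    outlier_frac: float = 0.05
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    myofibril_angle_rad: float = 0.3
    myofibril_width_nm: float = 900.0
    n_frames: int = 15000
    seed: int = 0

    def validate(self) -> None:
        if self.n_sarcomeres < 1:
            raise ValidationError("n_sarcomeres must be >= 1")
        if self.sarcomere_mean_nm <= 0:
            raise ValidationError("sarcomere_mean_nm must be positive")
        if not (0 <= self.sarcomere_sd_nm < self.sarcomere_mean_nm / 3):
            raise ValidationError("sarcomere_sd_nm must be < period / 3")
        if not self.epitopes:
            raise ValidationError("epitopes must be non-empty")
        for ep in self.epitopes:
            ep.validate()
        if self.loc_precision_nm < 0:
            raise ValidationError("loc_precision_nm must be >= 0")
        if self.background_per_um < 0:
            raise ValidationError("background_per_um must be >= 0")
        if not (0 <= self.outlier_frac < 1):
            raise ValidationError("outlier_frac must be in [0, 1)")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if self.myofibril_width_nm <= 0:
            raise ValidationError("myofibril_width_nm must be positive")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


@dataclass
class GroundTruth:
    """What the generator knows: the geometry behind every row.

    ``zdisc_positions_nm`` are in the pick frame (axial nm, pick centre at
    0).  ``offsets_by_zdisc`` maps epitope label -> per-Z-disc jittered
    offsets (the per-sarcomere truth the pipeline should recover on
    average).  ``provenance`` maps channel label -> per-row tag in
    {band, background, outlier}, partitioning each table's rows.
    """

    zdisc_positions_nm: np.ndarray
    epitope_offsets_nm: dict[str, float]
    offsets_by_zdisc: dict[str, np.ndarray]
    provenance: dict[str, np.ndarray]
    sarcomere_lengths_nm: np.ndarray


def _make_lattice(config: SimConfig, rng: np.random.Generator):
    spacings = config.sarcomere_mean_nm + config.sarcomere_sd_nm * \
        rng.standard_normal(config.n_sarcomeres)
    z = AXIS_MARGIN_NM + np.concatenate([[0.0], np.cumsum(spacings)])
    total_len = z[-1] + AXIS_MARGIN_NM
    return z, spacings, total_len


def _draw_channel(
    config: SimConfig,
    z_axial_nm: np.ndarray,
    total_len_nm: float,
    rng: np.random.Generator,
):
    """Draw band + background + outlier rows for one channel, axis frame.

    Returns (u, v, provenance, offsets_by_zdisc); u is axial nm, v
    transverse nm.
    """
    transverse_sd = config.myofibril_width_nm / 2
    axial_sd = math.hypot  # reused below
    u_parts: list[np.ndarray] = []
    v_parts: list[np.ndarray] = []
    tags: list[np.ndarray] = []
    offsets_by_zdisc: dict[str, np.ndarray] = {}
    band_centers: list[float] = []
    band_sigmas: list[float] = []

    for ep in config.epitopes:
        sd = math.hypot(ep.band_sigma_nm, config.loc_precision_nm)
        offs = ep.offset_nm + ep.offset_sd_nm * \
            rng.standard_normal(len(z_axial_nm))
        offsets_by_zdisc[ep.label] = offs
        for z, off in zip(z_axial_nm, offs):
            for side in (-1.0, +1.0):
                center = z + side * off
                n = ep.n_locs_per_band
                u_parts.append(center + sd * rng.standard_normal(n))
                v_parts.append(transverse_sd * rng.standard_normal(n))
                tags.append(np.full(n, "band", dtype=object))
                band_centers.append(center)
                band_sigmas.append(sd)

    n_bg = rng.poisson(config.background_per_um * total_len_nm / 1000.0)
    if n_bg:
        u_parts.append(rng.uniform(0.0, total_len_nm, n_bg))
        v_parts.append(transverse_sd * rng.standard_normal(n_bg))
        tags.append(np.full(n_bg, "background", dtype=object))

    n_signal = sum(len(p) for p in u_parts)
    n_out = int(round(config.outlier_frac / (1 - config.outlier_frac) * n_signal))
    if n_out:
        # multi-emitter artifacts cluster near bands with ~doubled spread
        pick = rng.integers(0, len(band_centers), n_out)
        centers = np.array(band_centers)[pick]
        sds = 2.0 * np.array(band_sigmas)[pick]
        u_parts.append(centers + sds * rng.standard_normal(n_out))
        v_parts.append(transverse_sd * rng.standard_normal(n_out))
        tags.append(np.full(n_out, "outlier", dtype=object))

    u = np.concatenate(u_parts)
    v = np.concatenate(v_parts)
    provenance = np.concatenate(tags)
    return u, v, provenance, offsets_by_zdisc


def _assemble_table(
    config: SimConfig,
    u_nm: np.ndarray,
    v_nm: np.ndarray,
    provenance: np.ndarray,
    total_len_nm: float,
    rng: np.random.Generator,
    channel_label: str,
) -> LocalizationTable:
    n = len(u_nm)
    is_out = provenance == "outlier"
    sx = NOMINAL_PSF_WIDTH_PX + PSF_WIDTH_SD_PX * rng.standard_normal(n)
    sy = NOMINAL_PSF_WIDTH_PX + PSF_WIDTH_SD_PX * rng.standard_normal(n)
    n_out = int(is_out.sum())
    if n_out:
        sx[is_out] += rng.uniform(*OUTLIER_SHIFT_PX, n_out)
        sy[is_out] += rng.uniform(*OUTLIER_SHIFT_PX, n_out)
    sx = np.clip(sx, 0.1, None)
    sy = np.clip(sy, 0.1, None)

    frame = rng.integers(0, config.n_frames, n)
    photons = rng.lognormal(mean=math.log(3000.0), sigma=0.5, size=n)

    theta = config.myofibril_angle_rad
    c, s = math.cos(theta), math.sin(theta)
    u_rel = u_nm - total_len_nm / 2
    px = config.pixel_size_nm
    x = SCENE_CENTER_PX[0] + (c * u_rel - s * v_nm) / px
    y = SCENE_CENTER_PX[1] + (s * u_rel + c * v_nm) / px
    return LocalizationTable(
        frame=frame, x=x, y=y, photons=photons, sx=sx, sy=sy,
        pixel_size_nm=config.pixel_size_nm, channel_label=channel_label,
    )


def _make_pick(config: SimConfig, total_len_nm: float) -> PickRegion:
    px = config.pixel_size_nm
    return PickRegion(
        center_x=SCENE_CENTER_PX[0],
        center_y=SCENE_CENTER_PX[1],
        length=total_len_nm / px,
        width=3 * config.myofibril_width_nm / px,
        angle=config.myofibril_angle_rad,
    )


def simulate_myofibril(
    config: SimConfig,
) -> tuple[LocalizationTable, PickRegion, GroundTruth]:
    """Simulate one myofibril; deterministic given ``config.seed``."""
    config.validate()
    geom_rng, chan_rng = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(2)
    ]
    z_nm, spacings, total_len = _make_lattice(config, geom_rng)
    u, v, provenance, offsets = _draw_channel(config, z_nm, total_len, chan_rng)
    label = config.epitopes[0].channel_label or "ch0"
    table = _assemble_table(config, u, v, provenance, total_len, chan_rng, label)
    truth = GroundTruth(
        zdisc_positions_nm=z_nm - total_len / 2,
        epitope_offsets_nm={ep.label: ep.offset_nm for ep in config.epitopes},
        offsets_by_zdisc=offsets,
        provenance={label: provenance},
        sarcomere_lengths_nm=spacings,
    )
    return table, _make_pick(config, total_len), truth


def simulate_two_colour(
    config_a: SimConfig,
    config_b: SimConfig,
    shared_geometry: bool = True,
) -> tuple[LocalizationTable, LocalizationTable, PickRegion, GroundTruth]:
    """Two channels over one myofibril, as in dual-colour imaging.

    With ``shared_geometry`` both channels see the identical Z-disc
    lattice and orientation (geometry drawn from ``config_a``); band and
    background draws stay independent per channel.  Without it, each
    channel gets its own lattice (Z-disc counts may differ).
    """
    config_a.validate()
    config_b.validate()
    if config_a.pixel_size_nm != config_b.pixel_size_nm:
        raise ValidationError("channels must share pixel_size_nm")

    if not shared_geometry:
        table_a, pick, truth_a = simulate_myofibril(config_a)
        table_b, _, truth_b = simulate_myofibril(config_b)
        truth = GroundTruth(
            zdisc_positions_nm=truth_a.zdisc_positions_nm,
            epitope_offsets_nm={**truth_a.epitope_offsets_nm,
                                **truth_b.epitope_offsets_nm},
            offsets_by_zdisc={**truth_a.offsets_by_zdisc,
                              **truth_b.offsets_by_zdisc},
            provenance={**truth_a.provenance, **truth_b.provenance},
            sarcomere_lengths_nm=truth_a.sarcomere_lengths_nm,
        )
        return table_a, table_b, pick, truth

    seeds = np.random.SeedSequence(config_a.seed).spawn(3)
    geom_rng = np.random.default_rng(seeds[0])
    z_nm, spacings, total_len = _make_lattice(config_a, geom_rng)

    geo_b = replace(config_b,
                    n_sarcomeres=config_a.n_sarcomeres,
                    sarcomere_mean_nm=config_a.sarcomere_mean_nm,
                    sarcomere_sd_nm=config_a.sarcomere_sd_nm,
                    myofibril_angle_rad=config_a.myofibril_angle_rad)

    tables = []
    provenance: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    for i, cfg in enumerate((config_a, geo_b)):
        rng = np.random.default_rng(seeds[i + 1])
        u, v, prov, offs = _draw_channel(cfg, z_nm, total_len, rng)
        label = cfg.epitopes[0].channel_label or f"ch{i}"
        tables.append(
            _assemble_table(cfg, u, v, prov, total_len, rng, label))
        provenance[label] = prov
        offsets.update(offs)

    truth = GroundTruth(
        zdisc_positions_nm=z_nm - total_len / 2,
        epitope_offsets_nm={
            ep.label: ep.offset_nm
            for cfg in (config_a, config_b) for ep in cfg.epitopes
        },
        offsets_by_zdisc=offsets,
        provenance=provenance,
        sarcomere_lengths_nm=spacings,
    )
    return tables[0], tables[1], _make_pick(config_a, total_len), truth
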