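"""End-to-end orchestration: filter -> rotate -> detect -> extract -> stats.

One :class:`PipelineConfig` (usually loaded from YAML) drives a full run
over any number of channels and picks.  Per-myofibril failures are
recorded as skip reasons and never abort the run; the run fails only when
no myofibril yields measurements.  All randomness flows from the single
top-level seed, so identical config + inputs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BandParams, EpitopeMeasurement, extract_epitope_pairs
from .emitter_filter import FilterParams, filter_multi_emitter
from .errors import SarcopaintError, ValidationError
from .geometry import project_profile, rotate_to_pick_axis
from .locio import (BAND_COLUMNS, LocalizationTable, PickRegion,
                    read_localizations, read_picks, write_band_table)
from .sarcostats import (bootstrap_mean, half_distance_series, known_labels,
                         ordering_fraction)
from .zdisc import ZDiscSet, detect_zdiscs, sarcomere_lengths

logger = logging.getLogger("sarcopaint")

MEASUREMENT_COLUMNS = (
    "myofibril_id", "zdisc_id", "channel_label", "epitope_label",
    "left_center_nm", "right_center_nm", "separation_nm",
    "half_distance_nm", "zdisc_reference_nm",
)


@dataclass
class ChannelInput:
    path: str
    channel_label: str
    format: str | None = None


@dataclass
class ZDiscParams:
    bin_size_nm: float = 130.0
    expected_sarcomere_nm: float = 3500.0
    tolerance_frac: float = 0.25
    min_prominence_frac: float = 0.2


@dataclass
class StatsParams:
    n_replicates: int = 1000
    pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PipelineConfig:
    channels: list[ChannelInput]
    picks_path: str
    epitope_map: dict[str, list[str]]
    output_dir: str = "sarcopaint_run"
    pixel_size_nm: float = 130.0
    filter_enabled: bool = True
    filter_params: FilterParams = field(default_factory=FilterParams)
    zdisc_params: ZDiscParams = field(default_factory=ZDiscParams)
    band_params: BandParams = field(default_factory=BandParams)
    stats_params: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        channels = [ChannelInput(**c) for c in raw["inputs"]["channels"]]
        stats_raw = dict(raw.get("stats", {}))
        stats = StatsParams(
            n_replicates=int(stats_raw.get("n_replicates", 1000)),
            pairs=[tuple(p) for p in stats_raw.get("pairs", [])],
        )
        return cls(
            channels=channels,
            picks_path=raw["inputs"]["picks"],
            epitope_map={k: list(v) for k, v in raw["epitope_map"].items()},
            output_dir=raw.get("output_dir", "sarcopaint_run"),
            pixel_size_nm=float(raw.get("pixel_size_nm", 130.0)),
            filter_enabled=bool(raw.get("filter", {}).get("enabled", True)),
            filter_params=FilterParams(
                **{k: v for k, v in raw.get("filter", {}).items()
                   if k in ("radius_px", "hist_bin_px")}),
            zdisc_params=ZDiscParams(**raw.get("zdisc", {})),
            band_params=BandParams(**raw.get("bands", {})),
            stats_params=stats,
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


@dataclass
class MyofibrilResult:
    myofibril_id: int
    n_locs_in: int
    n_locs_after_filter: int
    n_zdiscs: int
    n_zdiscs_skipped: int
    skip_reasons: dict[str, int]
    measurements: list[EpitopeMeasurement]
    sarcomere_length_by_zdisc: dict[tuple[int, int], float]


@dataclass
class RunReport:
    myofibrils: list[MyofibrilResult]
    band_table_path: str | None
    measurements_path: str | None
    summary_path: str | None
    config_echo_path: str | None
    version: str = __version__


def local_sarcomere_lengths(
    zdiscs: ZDiscSet, myofibril_id: int
) -> dict[tuple[int, int], float]:
    """Per-Z-disc local period: mean of the adjacent spacings."""
    lengths = sarcomere_lengths(zdiscs)
    out: dict[tuple[int, int], float] = {}
    for zid in range(len(zdiscs)):
        adjacent = []
        if zid - 1 >= 0 and zid - 1 < len(lengths):
            adjacent.append(lengths[zid - 1])
        if zid < len(lengths):
            adjacent.append(lengths[zid])
        if adjacent:
            out[(myofibril_id, zid)] = float(np.mean(adjacent))
    return out


def analyze_myofibril(
    tables: Sequence[LocalizationTable],
    pick: PickRegion,
    epitope_map: Mapping[str, Sequence[str]],
    myofibril_id: int = 0,
    filter_enabled: bool = True,
    filter_params: FilterParams | None = None,
    zdisc_params: ZDiscParams | None = None,
    band_params: BandParams | None = None,
) -> MyofibrilResult:
    """Run one pick through the whole chain.

    Z-discs are detected on the union of all channels' localizations;
    bands are extracted per channel with that channel's ordered epitope
    labels (innermost first).
    """
    filter_params = filter_params or FilterParams()
    zdisc_params = zdisc_params or ZDiscParams()
    band_params = band_params or BandParams()

    n_in = sum(len(t) for t in tables)
    rotated: list[LocalizationTable] = []
    for table in tables:
        if filter_enabled and len(table):
            table = filter_multi_emitter(table, filter_params)
        rotated.append(rotate_to_pick_axis(table, pick))
    n_filtered = sum(len(t) for t in rotated)

    # coarse profile over the union of channels (shared Z-disc lattice)
    union_x = np.concatenate([t.x for t in rotated]) if rotated else np.empty(0)
    union = LocalizationTable(
        frame=np.zeros(len(union_x), dtype=int), x=union_x,
        y=np.zeros(len(union_x)), photons=np.ones(len(union_x)),
        sx=np.ones(len(union_x)), sy=np.ones(len(union_x)),
        pixel_size_nm=tables[0].pixel_size_nm,
    ) if len(union_x) else None

    if union is None:
        zdiscs = ZDiscSet(np.empty(0), zdisc_params.expected_sarcomere_nm,
                          zdisc_params.tolerance_frac)
    else:
        profile = project_profile(union, zdisc_params.bin_size_nm)
        zdiscs = detect_zdiscs(
            profile,
            expected_sarcomere_nm=zdisc_params.expected_sarcomere_nm,
            tolerance_frac=zdisc_params.tolerance_frac,
            min_prominence_frac=zdisc_params.min_prominence_frac,
        )

    measurements: list[EpitopeMeasurement] = []
    skip_reasons: dict[str, int] = {}
    skipped_ids: set[int] = set()
    for table in rotated:
        labels = epitope_map.get(table.channel_label)
        if labels is None:
            raise ValidationError(
                f"epitope_map lacks channel '{table.channel_label}'")
        ms, skips = extract_epitope_pairs(
            table, zdiscs, band_params, tuple(labels),
            myofibril_id=myofibril_id,
            coarse_bin_nm=zdisc_params.bin_size_nm,
        )
        measurements.extend(ms)
        for s in skips:
            skip_reasons[s.reason] = skip_reasons.get(s.reason, 0) + 1
            skipped_ids.add(s.zdisc_id)

    return MyofibrilResult(
        myofibril_id=myofibril_id,
        n_locs_in=n_in,
        n_locs_after_filter=n_filtered,
        n_zdiscs=len(zdiscs),
        n_zdiscs_skipped=len(skipped_ids),
        skip_reasons=skip_reasons,
        measurements=measurements,
        sarcomere_length_by_zdisc=local_sarcomere_lengths(zdiscs, myofibril_id),
    )


def measurements_to_frame(
    measurements: Sequence[EpitopeMeasurement],
) -> pd.DataFrame:
    rows = [
        {
            "myofibril_id": m.myofibril_id,
            "zdisc_id": m.zdisc_id,
            "channel_label": m.channel_label,
            "epitope_label": m.epitope_label,
            "left_center_nm": m.left_band.center_nm,
            "right_center_nm": m.right_band.center_nm,
            "separation_nm": m.separation_nm,
            "half_distance_nm": m.half_distance_nm,
            "zdisc_reference_nm": m.zdisc_reference_nm,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def band_table_from_measurements(
    measurements: Sequence[EpitopeMeasurement],
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for side, band in (("left", m.left_band), ("right", m.right_band)):
            rows.append({
                "myofibril_id": m.myofibril_id,
                "zdisc_id": m.zdisc_id,
                "channel_label": m.channel_label,
                "epitope_label": m.epitope_label,
                "side": side,
                "center_nm": band.center_nm,
                "sigma_nm": band.sigma_nm,
                "amplitude": band.amplitude,
                "n_localizations": band.n_localizations,
            })
    return pd.DataFrame(rows, columns=list(BAND_COLUMNS))


def summarize(
    measurements: Sequence[EpitopeMeasurement],
    stats_params: StatsParams,
    seed: int,
) -> dict:
    """Per-epitope bootstrap summaries plus per-pair ordering counts."""
    summary: dict = {"epitopes": {}, "pairs": {}}
    for i, label in enumerate(known_labels(measurements)):
        values = half_distance_series(measurements, label)
        res = bootstrap_mean(values, n_replicates=stats_params.n_replicates,
                             seed=seed + i)
        summary["epitopes"][label] = asdict(res)
    for a, b in stats_params.pairs:
        res = ordering_fraction(measurements, a, b)
        summary["pairs"][f"{a}<{b}"] = {
            "n_closer": res.n_closer,
            "n_total": res.n_total,
            "mean_offset_nm": res.mean_offset_nm,
        }
    return summary


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages for every channel and pick; write outputs."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tables = [
        read_localizations(ch.path, format=ch.format,
                           pixel_size_nm=config.pixel_size_nm,
                           channel_label=ch.channel_label)
        for ch in config.channels
    ]
    picks = read_picks(config.picks_path)

    results: list[MyofibrilResult] = []
    all_measurements: list[EpitopeMeasurement] = []
    for mid, pick in enumerate(picks):
        try:
            res = analyze_myofibril(
                tables, pick, config.epitope_map, myofibril_id=mid,
                filter_enabled=config.filter_enabled,
                filter_params=config.filter_params,
                zdisc_params=config.zdisc_params,
                band_params=config.band_params,
            )
        except SarcopaintError as exc:
            logger.warning("myofibril %d failed: %s", mid, exc)
            continue
        logger.info("myofibril %d: %d Z-discs, %d measurements, %d skipped",
                    mid, res.n_zdiscs, len(res.measurements),
                    res.n_zdiscs_skipped)
        results.append(res)
        all_measurements.extend(res.measurements)

    if not all_measurements:
        raise SarcopaintError("no myofibril produced measurements")

    bands_path = out_dir / "bands.csv"
    write_band_table(bands_path, band_table_from_measurements(all_measurements))
    meas_path = out_dir / "measurements.csv"
    measurements_to_frame(all_measurements).to_csv(
        meas_path, index=False, float_format="%.6f")
    summary = summarize(all_measurements, config.stats_params, config.seed)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    echo_path = out_dir / "config_echo.yaml"
    echo_path.write_text(yaml.safe_dump(_config_as_dict(config),
                                        sort_keys=False))

    return RunReport(
        myofibrils=results,
        band_table_path=str(bands_path),
        measurements_path=str(meas_path),
        summary_path=str(summary_path),
        config_echo_path=str(echo_path),
    )


def _config_as_dict(config: PipelineConfig) -> dict:
    return {
        "inputs": {
            "channels": [asdict(c) for c in config.channels],
            "picks": config.picks_path,
        },
        "epitope_map": config.epitope_map,
        "output_dir": config.output_dir,
        "pixel_size_nm": config.pixel_size_nm,
        "filter": {"enabled": config.filter_enabled,
                   **asdict(config.filter_params)},
        "zdisc": asdict(config.zdisc_params),
        "bands": asdict(config.band_params),
        "stats": {"n_replicates": config.stats_params.n_replicates,
                  "pairs": [list(p) for p in config.stats_params.pairs]},
        "seed": config.seed,
        "log_level": config.log_level,
        "version": __version__,
    }
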