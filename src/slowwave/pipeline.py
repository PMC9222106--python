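"""Configuration-driven orchestration of the analysis stages.

A run is described by a YAML config holding an input manifest (recording
paths plus metadata), per-module parameter blocks and stage toggles.  Each
stage writes its outputs as CSV/JSON under the output directory; the final
report aggregates per-animal metrics and cohort statistics with enough
provenance (config hash, seeds, package version) to reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    DegenerateInputError,
    Hemisphere,
    PairedTable,
    Recording,
    SampleSizeError,
    group_test,
    load_recording,
)
from .events import (
    BurstParams,
    SpikeEventParams,
    classify_phenotype,
    detect_beta_bursts,
    detect_hypersync_spikes,
    event_rate,
    phase_locking,
)
from .spectral import fit_spectral_exponent, welch_psd
from .swa import UpDownParams, detect_updown, swa_metrics, us_slopes
from .units import UnitParams, extract_units, unit_rate, units_in_us

log = logging.getLogger("slowwave.pipeline")

__all__ = ["RunConfig", "Report", "run_all", "summarize_cohort", "analyze_recording"]

STAGES = ("swa", "events", "units", "spectrum")


@dataclass
class RunConfig:
    manifest: list[dict]
    out_dir: Path
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    updown: UpDownParams = field(default_factory=UpDownParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    spikes: SpikeEventParams = field(default_factory=SpikeEventParams)
    units: UnitParams = field(default_factory=UnitParams)
    exponent_model: str = "semilog_exponential"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        manifest = raw.get("manifest", [])
        for entry in manifest:
            p = Path(entry["path"])
            if not p.exists():
                raise FileNotFoundError(f"manifest entry does not exist: {p}")
        kwargs = {
            "manifest": manifest,
            "out_dir": Path(raw.get("out_dir", "slowwave_out")),
            "seed": int(raw.get("seed", 0)),
            "log_level": raw.get("log_level", "INFO"),
            "exponent_model": raw.get("exponent_model", "semilog_exponential"),
        }
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        for key, cls_ in (
            ("updown", UpDownParams),
            ("bursts", BurstParams),
            ("spikes", SpikeEventParams),
            ("units", UnitParams),
        ):
            if key in raw:
                kwargs[key] = cls_(**raw[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "manifest": self.manifest,
                "stages": list(self.stages),
                "seed": self.seed,
                "updown": vars(self.updown),
                "bursts": {k: str(v) for k, v in vars(self.bursts).items()},
                "spikes": {k: str(v) for k, v in vars(self.spikes).items()},
                "units": {k: str(v) for k, v in vars(self.units).items()},
                "exponent_model": self.exponent_model,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Report:
    per_animal: dict
    group_stats: dict
    phenotypes: dict
    failures: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "per_animal": self.per_animal,
            "group_stats": self.group_stats,
            "phenotypes": self.phenotypes,
            "failures": self.failures,
            "provenance": self.provenance,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _hemi_labels(rec: Recording) -> tuple[str | None, str | None]:
    inv: dict[Hemisphere, str] = {}
    for lbl, h in rec.hemisphere_map.items():
        inv.setdefault(h, lbl)
    return inv.get(Hemisphere.injected), inv.get(Hemisphere.control_hemisphere)


def analyze_recording(rec: Recording, cfg: RunConfig, out_dir: Path | None = None) -> dict:
    """Run the enabled stages on one recording; returns the per-animal block."""
    inj, ctl = _hemi_labels(rec)
    result: dict = {"animal_id": rec.animal_id, "group": rec.group.value}
    if inj is None and ctl is None:
        raise ValueError(f"{rec.animal_id}: no hemisphere-tagged channels")

    segs = {}
    if "swa" in cfg.stages or "events" in cfg.stages or "units" in cfg.stages:
        for lbl in filter(None, {inj, ctl}):
            segs[lbl] = detect_updown(rec[lbl], cfg.updown)
            log.info("%s/%s: %d up states", rec.animal_id, lbl, len(segs[lbl].us))

    if "swa" in cfg.stages:
        if inj and ctl:
            paired = swa_metrics(rec, segs, inj, ctl)
            result["swa"] = paired.df.to_dict(orient="records")
            if out_dir:
                paired.to_csv(out_dir / f"{rec.animal_id}_swa.csv")
                for lbl in (inj, ctl):
                    segs[lbl].us.to_csv(out_dir / f"{rec.animal_id}_{lbl}_us.csv")
        else:
            log.warning("%s: missing hemisphere, unpaired SWA only", rec.animal_id)
            lbl = inj or ctl
            from .spectral import DELTA, band_rms

            result["swa_unpaired"] = {
                "channel": lbl,
                "delta_rms": band_rms(rec[lbl], DELTA),
                **us_slopes(rec[lbl], segs[lbl]).summary(),
            }

    if "events" in cfg.stages and inj:
        ts = rec[inj]
        bursts = detect_beta_bursts(ts, cfg.bursts)
        spikes = detect_hypersync_spikes(ts, cfg.spikes)
        beta_rate = event_rate(bursts, ts.duration)
        spike_rate = event_rate(spikes, ts.duration)
        result["events"] = {
            "n_beta_bursts": len(bursts),
            "n_hypersync": len(spikes),
            "beta_rate_per_hour": beta_rate,
            "hypersync_rate_per_hour": spike_rate,
            "phenotype": classify_phenotype(beta_rate, spike_rate).to_dict(),
        }
        log.info(
            "%s: %d bursts (%.1f/h), %d hypersync (%.1f/h)",
            rec.animal_id, len(bursts), beta_rate, len(spikes), spike_rate,
        )
        if ctl and len(spikes) >= 5:
            pl = phase_locking(
                spikes, segs[ctl].us, (ts.t0, ts.t0 + ts.duration)
            )
            result["events"]["phase_locking"] = pl.to_dict()
        if out_dir:
            bursts.to_csv(out_dir / f"{rec.animal_id}_bursts.csv")
            spikes.to_csv(out_dir / f"{rec.animal_id}_hypersync.csv")

    if "units" in cfg.stages:
        result["units"] = {}
        for side, lbl in (("injected", inj), ("control_hemisphere", ctl)):
            if lbl is None:
                continue
            try:
                st = extract_units(rec[lbl], cfg.units)
            except ValueError as exc:
                result["units"][side] = {"error": str(exc)}
                continue
            block = {
                "n_spikes": st.n,
                "rate_hz": unit_rate(st, rec[lbl].duration),
                "threshold_mv": st.threshold_mv,
            }
            if lbl in segs:
                block["in_us"] = units_in_us(st, segs[lbl])
            result["units"][side] = block

    if "spectrum" in cfg.stages:
        result["spectrum"] = {}
        for side, lbl in (("injected", inj), ("control_hemisphere", ctl)):
            if lbl is None:
                continue
            spec = welch_psd(rec[lbl])
            fit = fit_spectral_exponent(spec, model=cfg.exponent_model)
            result["spectrum"][side] = fit.to_dict()
            if out_dir:
                spec.to_frame().to_csv(out_dir / f"{rec.animal_id}_{lbl}_psd.csv", index=False)
    return result


def run_all(cfg: RunConfig) -> Report:
    """Execute all stages on every manifest entry and assemble the report.

    A failing stage marks that animal/stage failed in the report and the
    run continues; the caller decides the exit code from ``failures``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_animal, failures, phenotypes = {}, {}, {}
    for entry in cfg.manifest:
        rec = load_recording(entry["path"], entry.get("format"))
        if "animal_id" in entry:
            rec.animal_id = entry["animal_id"]
        try:
            block = analyze_recording(rec, cfg, out_dir)
            per_animal[rec.animal_id] = block
            if "events" in block:
                phenotypes[rec.animal_id] = block["events"]["phenotype"]
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log.error("%s failed: %s", rec.animal_id, exc)
            failures[rec.animal_id] = str(exc)

    group_stats = summarize_cohort(per_animal)
    report = Report(
        per_animal=per_animal,
        group_stats=group_stats,
        phenotypes=phenotypes,
        failures=failures,
        provenance={
            "config_hash": cfg.config_hash(),
            "package_version": __version__,
            "seed": cfg.seed,
        },
    )
    report.write(out_dir / "report.json")
    return report


def summarize_cohort(per_animal: dict) -> dict:
    """Cohort statistics per metric.

    Paired Wilcoxon (injected vs control hemisphere) within mosaic animals;
    Mann-Whitney of injected-side values, mosaic vs control animals.
    Metrics with undersized or degenerate samples are skipped with a
    reason.
    """
    rows = []
    for animal, block in per_animal.items():
        for rec_ in block.get("swa", []):
            rows.append({**rec_, "group": block["group"]})
    if not rows:
        return {}
    df = pd.DataFrame(rows)
    out: dict = {}
    for metric, sub in df.groupby("metric"):
        entry: dict = {}
        mosaic = sub[sub["group"] != "control"]
        control = sub[sub["group"] == "control"]
        try:
            res = group_test(
                (mosaic["value_injected"].to_numpy(), mosaic["value_control_hemisphere"].to_numpy()),
                method="wilcoxon_paired",
            )
            diff = float(
                (mosaic["value_injected"] - mosaic["value_control_hemisphere"]).median()
            )
            entry["paired_wilcoxon"] = {
                **res.to_dict(),
                "direction": "injected<control" if diff < 0 else "injected>=control",
            }
        except (SampleSizeError, DegenerateInputError) as exc:
            entry["paired_wilcoxon"] = {"skipped": str(exc)}
        try:
            res = group_test(
                mosaic["value_injected"].to_numpy(),
                method="mann_whitney",
                values_b=control["value_injected"].to_numpy(),
            )
            entry["mann_whitney_vs_control"] = res.to_dict()
        except (SampleSizeError, DegenerateInputError, ValueError) as exc:
            entry["mann_whitney_vs_control"] = {"skipped": str(exc)}
        out[metric] = entry
    return out
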