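"""End-to-end analysis pipeline: load/simulate -> filter -> fit -> derive.

A single :class:`RunConfig` (optionally read from YAML) drives the whole
run.  All randomness flows from one master seed, split deterministically per
stage with :class:`numpy.random.SeedSequence`, so a config + seed pair maps
to one bundle of results, byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .data import ExperimentTable, read_plant_table, split_monoculture_biculture
from .metrics import ThresholdEstimate, rca, threshold_ci
from .models import (
    BicultureFit,
    MonocultureFit,
    coefficient_table,
    fit_biculture,
    fit_monoculture,
)
from .preprocess import (
    FilterReport,
    filter_outliers,
    null_filter_reports,
    prepare_log_response,
    reports_frame,
)

log = logging.getLogger("addseries")


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Exactly one of ``input_path`` (a per-plant CSV) or ``simulation`` (a
    :class:`addseries.simulate.DesignSpec` plus optional per-species
    parameter overrides) must be set.
    """

    input_path: str | None = None
    dialect: dict = field(default_factory=dict)
    simulation: dict | None = None  # DesignSpec fields + optional "params"
    filter_k: float | None = 1.5  # None disables the outlier screen
    declines: tuple = (0.5, 0.75)
    n_boot: int = 10_000
    seed: int = 0
    fit_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_path or simulation")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "declines" in raw:
            raw["declines"] = tuple(raw["declines"])
        return cls(**raw)


@dataclass
class ResultBundle:
    """Machine-readable results of one pipeline run."""

    filter_reports: list[FilterReport]
    monoculture_fits: dict[str, MonocultureFit]
    biculture_fits: dict[str, BicultureFit]
    thresholds: list[ThresholdEstimate]
    rca_results: dict[str, object]
    provenance: dict

    def to_dict(self) -> dict:
        def clean(obj):
            d = asdict(obj)
            for k, v in d.items():
                if isinstance(v, np.ndarray):
                    d[k] = v.tolist()
            return d

        return {
            "filter_reports": [clean(r) for r in self.filter_reports],
            "monoculture_fits": {s: clean(f) for s, f in self.monoculture_fits.items()},
            "biculture_fits": {s: clean(f) for s, f in self.biculture_fits.items()},
            "thresholds": [clean(t) for t in self.thresholds],
            "rca": {s: clean(r) for s, r in self.rca_results.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, raw: dict) -> "ResultBundle":
        def arr(d, keys):
            return {k: np.asarray(v) if k in keys else v for k, v in d.items()}

        from .metrics import RCAResult, ThresholdEstimate

        return cls(
            filter_reports=[FilterReport(**r) for r in raw["filter_reports"]],
            monoculture_fits={
                s: MonocultureFit(**arr(f, {"covariance", "theta"}))
                for s, f in raw["monoculture_fits"].items()
            },
            biculture_fits={
                s: BicultureFit(**arr(f, {"covariance", "theta"}))
                for s, f in raw["biculture_fits"].items()
            },
            thresholds=[ThresholdEstimate(**t) for t in raw["thresholds"]],
            rca_results={s: RCAResult(**r) for s, r in raw["rca"].items()},
            provenance=raw["provenance"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ResultBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}': {exc}") from exc

    return wrap


def _load_or_simulate(config: RunConfig, seed: int) -> ExperimentTable:
    if config.input_path is not None:
        return read_plant_table(config.input_path, config.dialect)
    spec_fields = {
        k: v for k, v in config.simulation.items() if k != "params"
    }
    spec_fields.setdefault("seed", seed)
    spec = sim.DesignSpec(**spec_fields)
    params = None
    if "params" in config.simulation:
        params = {
            sp: sim.SpeciesParams(**p) for sp, p in config.simulation["params"].items()
        }
    return sim.generate_dataset(spec, params)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute load/simulate -> validate -> filter -> split -> fit -> derive."""
    ss = np.random.SeedSequence(config.seed)
    data_seed, boot_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]

    table = _stage("load")(_load_or_simulate, config, data_seed)
    _stage("validate")(table.validate)
    log.info("loaded %d records from %d pots", len(table), table.frame.pot_id.nunique())

    if config.filter_k is None:
        filtered, reports = table, null_filter_reports(table)
    else:
        filtered, reports = _stage("filter")(filter_outliers, table, config.filter_k)
    log.info(
        "outlier filter: %d -> %d records", len(table), len(filtered)
    )

    mono, bi = _stage("split")(split_monoculture_biculture, filtered)
    mono_frame = _stage("log-response")(prepare_log_response, mono)
    bi_frame = _stage("log-response")(prepare_log_response, bi)

    species = sorted(filtered.frame["species"].unique())
    mono_fits: dict[str, MonocultureFit] = {}
    bi_fits: dict[str, BicultureFit] = {}
    for sp in species:
        mono_fits[sp] = _stage(f"fit-monoculture-{sp}")(
            fit_monoculture, mono_frame, species=sp, **config.fit_options
        )
        log.info(
            "%s monoculture: wm=%.4g a=%.4g b=%.4g (pseudo-r2 %.3f, n=%d)",
            sp, mono_fits[sp].wm, mono_fits[sp].a, mono_fits[sp].b,
            mono_fits[sp].pseudo_r2, mono_fits[sp].n,
        )
    for sp in species:
        bi_fits[sp] = _stage(f"fit-biculture-{sp}")(
            fit_biculture, bi_frame, mono_fits[sp].b, species=sp, **config.fit_options
        )
        log.info(
            "%s biculture: wm=%.4g beta=%.4g alpha=%.4g (pseudo-r2 %.3f, n=%d)",
            sp, bi_fits[sp].wm, bi_fits[sp].beta, bi_fits[sp].alpha,
            bi_fits[sp].pseudo_r2, bi_fits[sp].n,
        )

    thresholds: list[ThresholdEstimate] = []
    for i, sp in enumerate(species):
        for j, mode in enumerate(("intraspecific", "interspecific")):
            for k, f in enumerate(config.declines):
                thresholds.append(
                    _stage(f"threshold-{sp}-{mode}-{f}")(
                        threshold_ci,
                        bi_fits[sp],
                        mode,
                        f,
                        config.n_boot,
                        boot_seed + 100 * i + 10 * j + k,
                    )
                )
    rca_results = {
        sp: rca(bi_fits[sp].beta, bi_fits[sp].alpha, focal_species=sp)
        for sp in species
    }

    config_dict = asdict(config)
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    provenance = {
        "config": config_dict,
        "config_sha256": config_hash,
        "seed": config.seed,
        "stage_seeds": {"data": data_seed, "bootstrap": boot_seed},
        "n_records_in": len(table),
        "n_records_fitted": len(filtered),
    }
    return ResultBundle(reports, mono_fits, bi_fits, thresholds, rca_results, provenance)


def report_tables(bundle: ResultBundle, outdir: str | Path) -> list[Path]:
    """Write the result tables as CSV plus a plain-text summary (5 files)."""
    missing = [
        name
        for name, part in (
            ("filter_reports", bundle.filter_reports),
            ("monoculture_fits", bundle.monoculture_fits),
            ("biculture_fits", bundle.biculture_fits),
            ("thresholds", bundle.thresholds),
            ("rca", bundle.rca_results),
        )
        if not part
    ]
    if missing:
        raise PipelineError(f"bundle incomplete, missing sections: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    p = outdir / "filter_report.csv"
    reports_frame(bundle.filter_reports).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "monoculture_fits.csv"
    pd.DataFrame(
        [
            {
                "species": f.species,
                "wm": f.wm, "a": f.a, "b": f.b,
                "se_wm": f.se_wm, "se_a": f.se_a, "se_b": f.se_b,
                "pseudo_r2": f.pseudo_r2, "n": f.n,
            }
            for f in bundle.monoculture_fits.values()
        ]
    ).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "coefficients.csv"
    coefficient_table(list(bundle.biculture_fits.values())).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "thresholds.csv"
    pd.DataFrame(
        [
            {
                "species": t.focal_species,
                "experiment": t.mode,
                "decline_fraction": t.decline_fraction,
                "threshold_plants": round(t.n_star, 5),
                "ci_low": round(t.ci_low, 5),
                "ci_high": round(t.ci_high, 5),
            }
            for t in bundle.thresholds
        ]
    ).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "summary.txt"
    lines = ["addition-series competition analysis", ""]
    for sp, f in bundle.monoculture_fits.items():
        lines.append(
            f"{sp} monoculture: ln w = ln {f.wm:.5f} - {f.b:.5f} * "
            f"ln(1 + {f.a:.5f} N)   [pseudo-r2 {f.pseudo_r2:.2f}, n={f.n}]"
        )
    for sp, f in bundle.biculture_fits.items():
        lines.append(
            f"{sp} biculture:  ln w = ln {f.wm:.5f} - {f.b_fixed:.5f} * "
            f"ln(1 + {f.beta:.5f} N_self + {f.alpha:.5f} N_other)   "
            f"[pseudo-r2 {f.pseudo_r2:.2f}, n={f.n}]"
        )
    for sp, r in bundle.rca_results.items():
        lines.append(
            f"RCA({sp}) = {r.rca:.3f}; one conspecific is matched by "
            f"{r.density_equivalence:.2f} plants of the other species"
        )
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)
    return paths
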