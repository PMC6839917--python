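"""End-to-end analysis pipeline: analyze, sample, scatter, fit, report.

A single configuration drives the full chain: curve analysis (Guinier,
P(r), Vc), hinge sampling of a start model, per-member theoretical
curves, minimal ensemble search, and equilibrium-constant reporting.
Every intermediate is persisted (pool PDBs, member profiles, fits) and
the run is idempotent given the same configuration and seed: reports are
byte-identical across repeats.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .analysis import (
    estimate_dmax,
    guinier_fit,
    kratky,
    pair_distribution,
    volume_of_correlation,
)
from .ensemble import classify_members, equilibrium_constant, minimal_ensemble_search
from .errors import ConfigError
from .models import apply_domain_sidecar, read_calpha, write_calpha
from .profiles import read_dat, write_dat
from .sampling import sample_conformers, sgc_default_protocol
from .scattering import coordinate_rg, debye_profile
from .synthetic import make_two_state_benchmark

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("saxstate.pipeline")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    profile: str
    start_model: str
    output_dir: str
    seed: int | None = None
    dmax: float | str = "auto"
    dmax_grid: tuple[float, float, float] = (60.0, 200.0, 10.0)  # lo, hi, step
    n_samples_per_stage: int = 100
    max_angle: float = 40.0
    clash_cutoff: float = 3.5
    max_states: int = 3
    sampling_enabled: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown configuration keys: {sorted(extra)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        if isinstance(raw.get("dmax_grid"), (list, tuple)):
            raw["dmax_grid"] = tuple(raw["dmax_grid"])
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.sampling_enabled and self.seed is None:
            raise ConfigError(
                "a seed is mandatory when stochastic sampling is enabled"
            )
        for key in ("profile", "start_model"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")
        if isinstance(self.dmax, str) and self.dmax != "auto":
            raise ConfigError("dmax must be a number or 'auto'")
        if self.max_states < 1:
            raise ConfigError("max_states must be >= 1")

    def echo(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        d["dmax_grid"] = list(self.dmax_grid)
        return d


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all pipeline stages and return (and persist) the report.

    Stages, in order: curve analysis of the experimental profile,
    conformer sampling from the start model, theoretical curves for the
    start model plus the pool, minimal ensemble search, and
    equilibrium-constant computation.  A stage failure aborts the run
    with the stage name; outputs of completed stages are retained.

    The equilibrium constant counts a fitted member as extended when its
    coordinate-space Rg exceeds that of the start model.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict[str, Any] = {"config": config.echo()}
    stage = "analyze"
    try:
        profile = read_dat(config.profile)
        g = guinier_fit(profile)
        report["guinier"] = {
            "rg": g.rg,
            "i0": g.i0,
            "q_window": list(g.q_window),
            "n_points": g.n_points,
            "fit_quality": g.fit_quality,
        }
        if config.dmax == "auto":
            lo, hi, step = config.dmax_grid
            grid = np.arange(lo, hi + step / 2, step)
            dmax = estimate_dmax(profile, grid)
        else:
            dmax = float(config.dmax)
        pr = pair_distribution(profile, dmax)
        report["pr"] = {
            "dmax": pr.dmax,
            "chi2": pr.chi2,
            "smoothness": pr.regularization,
        }
        _write_tsv(out / "pr.tsv", ("r", "p"), np.column_stack([pr.r, pr.p]))
        kr = kratky(profile, g, normalized=True)
        _write_tsv(out / "kratky.tsv", ("qRg", "kratky"), np.column_stack([kr.x, kr.y]))
        vc = volume_of_correlation(profile, g)
        report["vc"] = {"vc": vc.vc, "qr": vc.qr, "mw_kda": vc.mw_kda}

        stage = "sample"
        start = read_calpha(config.start_model)
        sidecar = Path(config.start_model).with_suffix(".domains.json")
        if start.domain_labels is None and sidecar.exists():
            start = apply_domain_sidecar(start, sidecar)
        member_models = {"start": start}
        if config.sampling_enabled:
            protocol = sgc_default_protocol(
                start,
                n_samples_per_stage=config.n_samples_per_stage,
                max_angle=config.max_angle,
                seed=int(config.seed),  # type: ignore[arg-type]
                clash_cutoff=config.clash_cutoff,
            )
            pool = sample_conformers(start, protocol)
            pool_dir = out / "pool"
            pool_dir.mkdir(exist_ok=True)
            rows = []
            for c in pool:
                write_calpha(c.model, pool_dir / f"{c.member_id}.pdb")
                member_models[c.member_id] = c.model
                rows.append((c.member_id, c.stage, c.rmsd_to_start))
            with open(out / "pool_provenance.tsv", "w") as fh:
                fh.write("member_id\tstage\trmsd_to_start\n")
                for mid, st, rmsd in rows:
                    fh.write(f"{mid}\t{st}\t{rmsd:.4f}\n")
            report["pool"] = {"n_members": len(pool), "seed": config.seed}

        stage = "scatter"
        profiles_dir = out / "member_profiles"
        profiles_dir.mkdir(exist_ok=True)
        member_profiles = []
        for mid, model in member_models.items():
            p = debye_profile(model, profile.q, label=mid)
            write_dat(p, profiles_dir / f"{mid}.dat")
            member_profiles.append(p)

        stage = "mes"
        mes = minimal_ensemble_search(
            profile,
            member_profiles,
            max_states=config.max_states,
            seed=config.seed,
        )
        report["mes"] = {
            "selected_n": mes.selected_n,
            "per_n": {
                str(n): {
                    "chi2": f.chi2,
                    "members": list(f.member_ids),
                    "weights": [float(w) for w in f.weights],
                }
                for n, f in mes.per_n.items()
            },
        }

        stage = "keq"
        rg_start = coordinate_rg(start)
        selected = mes.selected
        extended_ids = [
            mid
            for mid in selected.member_ids
            if coordinate_rg(member_models[mid]) > rg_start
        ]
        keq = equilibrium_constant(selected, extended_ids)
        report["keq"] = {
            "value": keq if np.isfinite(keq) else "inf",
            "extended_members": extended_ids,
            "rule": "member Rg > start-model Rg",
        }
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out / "report.json")
    return report


def _write_tsv(path: Path, header: tuple[str, ...], rows: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in np.atleast_2d(rows):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
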