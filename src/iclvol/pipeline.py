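"""End-to-end orchestration: configuration, fixture generation, analysis and a
consolidated report.

``run_all`` ties the stages together: solution recipes -> chloride reversal
potential; simulated voltage-clamp cohorts -> I-V -> conductance -> Boltzmann
fits (isotonic, hypotonic, difference) per surgical group; synthetic swell
image cohorts -> segmentation -> normalized-area summaries; synthetic caspase
plate -> fold changes -> group comparisons.  Given a fixed configuration
(which must carry a seed for every stochastic stage) the report payload is
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import solutions as sol
from .ephys_sim import CellModel, ChannelModel, make_step_protocol, simulate_trace
from .ephys_fit import (
    conductance_transform,
    difference_current,
    estimate_reversal,
    fit_boltzmann,
    fit_difference_boltzmann,
    step_iv,
)
from .reference import recipe_path
from .swell_assay import (
    SwellModel,
    generate_cell_stack,
    generate_cohort,
    measure_stack,
    normalize_timecourse,
    summarize_groups,
)
from .caspase_stats import compare_groups, fold_change, generate_plate

__all__ = ["RunConfig", "Report", "load_config", "run_all"]

_STOCHASTIC_STAGES = ("ephys", "swell", "caspase")


@dataclass
class RunConfig:
    """Validated run configuration (see data/default_config.yaml for the schema)."""

    raw: dict

    def __post_init__(self) -> None:
        seeds = self.raw.get("seeds", {})
        missing = [s for s in _STOCHASTIC_STAGES if not isinstance(seeds.get(s), int)]
        if missing:
            raise ValueError(
                f"config must give an explicit integer seed for stage(s): {missing}"
            )
        for key in ("recipes", "analysis", "ephys", "swell", "caspase"):
            if key not in self.raw:
                raise ValueError(f"config is missing the {key!r} section")
        for name in self.raw["recipes"].values():
            self.resolve_recipe(name)  # raises if unresolvable

    def __getitem__(self, key):
        return self.raw[key]

    @staticmethod
    def resolve_recipe(name: str) -> Path:
        p = Path(name)
        if p.suffix == ".json" and p.exists():
            return p
        try:
            shipped = recipe_path(name)
        except FileNotFoundError:
            shipped = None
        if shipped is None or not shipped.exists():
            raise ValueError(f"recipe {name!r} is neither a file nor a shipped recipe")
        return shipped

    def sha256(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; ``None`` loads the shipped default."""
    if path is None:
        text = resources.files("iclvol").joinpath("data/default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    return RunConfig(yaml.safe_load(text))


@dataclass
class Report:
    """Consolidated run output; serializes to a deterministic JSON payload."""

    solutions: dict
    ephys: dict
    swell: dict
    caspase: dict
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _stage_seed(base: int, index: int) -> int:
    # derive distinct per-task seeds, kept within 32-bit range
    return int((base * 1000 + index) % (2**31 - 1))


def _solutions_stage(cfg: RunConfig) -> dict:
    pip = sol.load_recipe(cfg.resolve_recipe(cfg["recipes"]["pipette"]))
    bath = sol.load_recipe(cfg.resolve_recipe(cfg["recipes"]["bath"]))
    temp = float(cfg.raw.get("temperature_K", sol.DEFAULT_TEMPERATURE_K))
    c_in = sol.dissociate(pip)
    c_out = sol.dissociate(bath)
    ecl = sol.nernst_potential("cl", c_in["cl"], c_out["cl"], temp)
    return {
        "cl_in_mM": c_in["cl"],
        "cl_out_mM": c_out["cl"],
        "temperature_K": temp,
        "ecl_mV": ecl,
        "ecl_magnitude_rounded_mV": round(abs(ecl)),
        "bath_nominal_osmolarity_mOsm": sol.nominal_osmolarity(c_out),
        "pipette_nominal_osmolarity_mOsm": sol.nominal_osmolarity(c_in),
    }


def _fit_payload(fit) -> dict:
    return {
        "gmax_pS_per_pF": fit.gmax_pS_per_pF,
        "vh_mV": fit.vh_mV,
        "k_mV": fit.k_mV,
        "ci95": fit.ci95,
        "rss": fit.rss,
        "n_points": fit.n_points,
    }


def _ephys_stage(cfg: RunConfig) -> dict:
    e = cfg["ephys"]
    a = cfg["analysis"]
    erev = float(e["erev_mV"])
    protocol = make_step_protocol()
    jp = float(a.get("junction_potential_mV", 0.0))
    out: dict = {}
    for gi, (group, states) in enumerate(e["groups"].items()):
        iso = ChannelModel(erev_mV=erev, **states["iso"])
        hypo = ChannelModel(erev_mV=erev, **states["hypo"])
        cell = CellModel(
            iso=iso,
            hypo=hypo,
            capacitance_pF=float(e.get("capacitance_pF", 10.0)),
            noise_sd_pA=float(e.get("noise_sd_pA", 5.0)),
            seed=_stage_seed(cfg["seeds"]["ephys"], gi),
        )
        ivs = {}
        for ci, cond in enumerate(("iso", "hypo")):
            cell.seed = _stage_seed(cfg["seeds"]["ephys"], 10 * gi + ci)
            trace = simulate_trace(cell, protocol, condition=cond)
            iv = step_iv(trace, protocol, window_ms=tuple(a["window_ms"]), cell_id=group)
            if jp:
                iv.vm_mV = iv.vm_mV - jp
            ivs[cond] = iv
        fits = {}
        for cond in ("iso", "hypo"):
            curve = conductance_transform(
                ivs[cond], erev, float(a["exclusion_half_width_mV"])
            )
            fits[cond] = _fit_payload(
                fit_boltzmann(
                    curve,
                    ci_method=a["ci_method"],
                    n_boot=int(a.get("n_boot", 1000)),
                    seed=_stage_seed(cfg["seeds"]["ephys"], 100 + gi),
                )
            )
        diff_iv = difference_current(ivs["hypo"], ivs["iso"])
        fits["difference"] = _fit_payload(
            fit_difference_boltzmann(
                ivs["hypo"],
                ivs["iso"],
                erev,
                exclusion_half_width_mV=float(a["exclusion_half_width_mV"]),
                ci_method=a["ci_method"],
                n_boot=int(a.get("n_boot", 1000)),
                seed=_stage_seed(cfg["seeds"]["ephys"], 200 + gi),
            )
        )
        out[group] = {
            "fits": fits,
            "difference_reversal_mV": estimate_reversal(diff_iv, expected_mV=erev),
        }
    return out


def _swell_stage(cfg: RunConfig) -> dict:
    s = cfg["swell"]
    base_seed = cfg["seeds"]["swell"]
    courses = []
    for gi, (group, g) in enumerate(s["groups"].items()):
        base = SwellModel(
            initial_area_um2=float(g["initial_area_um2"]),
            plateau_relative_area=float(g["plateau_relative_area"]),
            rise_tau_s=float(s.get("rise_tau_s", 90.0)),
        )
        models = generate_cohort(
            group, int(g["n_cells"]), base, seed=_stage_seed(base_seed, gi)
        )
        for ci, model in enumerate(models):
            stack, _ = generate_cell_stack(model)
            areas = measure_stack(stack, model.um_per_px)
            courses.append(
                normalize_timecourse(
                    areas, model.times_s, cell_id=f"{group}_{ci:02d}", group=group
                )
            )
    table = summarize_groups(
        courses,
        t_eval_s=float(s.get("t_eval_s", 300.0)),
        seed=_stage_seed(base_seed, 900),
    )
    return {"summary": json.loads(table.to_json(orient="records"))}


def _caspase_stage(cfg: RunConfig) -> dict:
    c = cfg["caspase"]
    plate = generate_plate(
        folds={k: float(v) for k, v in c["folds"].items()},
        n_per_group=int(c.get("n_per_group", 20)),
        cv=float(c.get("cv", 0.06)),
        seed=_stage_seed(cfg["seeds"]["caspase"], 0),
    )
    folds = fold_change(plate)
    summaries, p_2w_vs_4w = compare_groups(
        folds, seed=_stage_seed(cfg["seeds"]["caspase"], 1)
    )
    def _clean(d: dict) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in d.items()}

    return {
        "groups": [_clean(dataclasses.asdict(s)) for s in summaries],
        "p_aclt2w_vs_aclt4w": None if np.isnan(p_2w_vs_4w) else p_2w_vs_4w,
    }


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> Report:
    """Run every stage and return (and optionally persist) the consolidated report."""
    report = Report(
        solutions=_solutions_stage(config),
        ephys=_ephys_stage(config),
        swell=_swell_stage(config),
        caspase=_caspase_stage(config),
        provenance={
            "config_sha256": config.sha256(),
            "seeds": config["seeds"],
            "iclvol_version": __version__,
        },
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
    return report
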