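"""Orchestration: simulation -> BWAS -> network -> ethogram, reproducibly.

A run is described by a :class:`RunConfig` (YAML or dict) holding exactly
one data source -- a simulation spec or paths to input CSVs -- plus stage
parameters and a mandatory master seed.  ``run_pipeline`` executes the
stages in dependency order, writes plain CSV/JSON artifacts, and always
writes a :class:`RunManifest` (config hash, per-stage seeds, artifact
paths, warnings), even when a stage fails part-way.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import counts as counts_mod
from . import ethogram as eth
from . import network as net
from .bwas import ContrastSpec, run_contrast
from .counts import ValidationError, read_count_table
from .synthetic import ConfigError, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    simulation: dict | None = None
    inputs: dict | None = None
    network: dict = field(
        default_factory=lambda: {"rho_min": 0.4, "target_fdr": 0.05, "alpha": 0.05}
    )
    ethogram: dict = field(
        default_factory=lambda: {"first_minutes": 5.0, "n_boot": 2000}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("config must set an explicit seed")
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "config must set exactly one of 'simulation' or 'inputs'"
            )
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=raw.get("seed"),
            outdir=raw.get("outdir", "fosnet_run"),
            simulation=raw.get("simulation"),
            inputs=raw.get("inputs"),
            network=raw.get("network", {"rho_min": 0.4, "target_fdr": 0.05,
                                        "alpha": 0.05}),
            ethogram=raw.get("ethogram", {"first_minutes": 5.0, "n_boot": 2000}),
        )

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "simulation": self.simulation,
            "inputs": {k: str(v) for k, v in self.inputs.items()}
            if self.inputs else None,
            "network": self.network,
            "ethogram": self.ethogram,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    artifacts: dict[str, str] = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; identical config + seed gives identical outputs."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.digest(), config.seed, __version__)
    manifest_path = outdir / "manifest.json"
    try:
        _run_stages(config, outdir, manifest)
    except Exception as exc:  # manifest must record partial failure
        manifest.warnings.append(f"{type(exc).__name__}: {exc}")
        if manifest.failed_stage is None:
            manifest.failed_stage = "unknown"
        logger.exception("pipeline stage %s failed", manifest.failed_stage)
    manifest.write(manifest_path)
    manifest.artifacts["manifest"] = str(manifest_path)
    manifest.write(manifest_path)
    return manifest


def _run_stages(config: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    # ---- stage: data ------------------------------------------------------
    manifest.failed_stage = "simulate"
    if config.simulation is not None:
        bundle = simulate_study(config.simulation or None, config.seed)
        manifest.stage_seeds = bundle.seed_log
        datasets = {}
        for name, sc in bundle.contrasts.items():
            path = outdir / f"counts_{name}.csv"
            counts_mod.write_count_table(sc.table, sc.meta, path)
            manifest.artifacts[f"counts/{name}"] = str(path)
            datasets[name] = (sc.table, sc.meta, sc.contrast)
        ethograms = bundle.ethograms
    else:
        table, meta = read_count_table(config.inputs["counts"])
        cspec = config.inputs["contrast"]
        contrast = ContrastSpec(
            treatment=cspec["treatment"], control=cspec["control"],
            bridge=cspec.get("bridge"),
        )
        datasets = {"input": (table, meta, contrast)}
        ethograms = _load_input_ethograms(config.inputs)

    # ---- stage: bwas ------------------------------------------------------
    manifest.failed_stage = "bwas"
    results = {}
    for name, (table, meta, contrast) in datasets.items():
        result = run_contrast(table, meta, contrast)
        path = outdir / f"bwas_{name}.csv"
        result.to_frame().to_csv(path)
        manifest.artifacts[f"bwas/{name}"] = str(path)
        results[name] = result

    # ---- stage: network ---------------------------------------------------
    manifest.failed_stage = "network"
    alpha = config.network.get("alpha", 0.05)
    for name, (table, meta, contrast) in datasets.items():
        significant = net.select_significant_regions(results[name], alpha)
        animals = meta.animals_in_group(contrast.treatment)
        if len(significant) < 3 or len(animals) < 4:
            manifest.warnings.append(
                f"network/{name}: skipped ({len(significant)} significant "
                f"regions, {len(animals)} animals)"
            )
            continue
        fractions = counts_mod.normalize_fractions(table)
        corr = net.spearman_matrix(fractions, animals, significant)
        sel = net.select_threshold(
            corr, config.network.get("target_fdr", 0.05),
            config.network.get("rho_min", 0.4),
        )
        graph = net.build_graph(
            corr, sel, counts_mod.synthetic_divisions(significant)
        )
        edges = outdir / f"network_{name}_edges.csv"
        graph.edge_frame().to_csv(edges, index=False)
        seljson = outdir / f"network_{name}_threshold.json"
        with open(seljson, "w") as fh:
            json.dump(sel.to_dict(), fh, indent=2)
        layout = outdir / f"network_{name}_layout.csv"
        net.mds_layout(corr).to_csv(layout)
        manifest.artifacts[f"network/{name}/edges"] = str(edges)
        manifest.artifacts[f"network/{name}/threshold"] = str(seljson)
        manifest.artifacts[f"network/{name}/layout"] = str(layout)

    # ---- stage: ethogram --------------------------------------------------
    manifest.failed_stage = "ethogram"
    if ethograms:
        _ethogram_stage(ethograms, outdir, manifest)
    manifest.failed_stage = None


def _load_input_ethograms(inputs: dict):
    ethograms: dict[str, dict[str, list[eth.Ethogram]]] = {}
    for spec in inputs.get("ethograms", []):
        e = eth.read_ethogram(
            spec["path"], day=spec.get("day", "day1"),
            animal=spec.get("animal", ""), group=spec.get("group", ""),
        )
        ethograms.setdefault(e.group, {}).setdefault(e.day, []).append(e)
    return ethograms


def _ethogram_stage(ethograms, outdir: Path, manifest: RunManifest) -> None:
    occ_rows = []
    ratios = {}
    shifts = {}
    for group, by_day in ethograms.items():
        day_occ = {}
        day_tm = {}
        for day, recs in by_day.items():
            occs, tms = [], []
            for e in recs:
                cut = int(round(300 * e.frame_rate))
                if cut >= len(e):  # short demo recordings: split in half
                    segs = {"first_half": (0, len(e) // 2),
                            "remainder": (len(e) // 2, len(e))}
                else:
                    segs = eth.default_segments(len(e), e.frame_rate)
                occ = eth.occupancy(e.states, segs, alphabet=e.alphabet)
                for seg_name in occ.index:
                    row = occ.loc[seg_name].to_dict()
                    row.update(group=group, day=day, animal=e.animal,
                               segment=seg_name)
                    occ_rows.append(row)
                whole = eth.occupancy(
                    e.states, {"all": (0, len(e))}, alphabet=e.alphabet
                ).loc["all"]
                occs.append(whole)
                tms.append(eth.transition_matrix(e.states, e.alphabet))
            day_occ[day] = pd.DataFrame(occs)
            day_tm[day] = tms
        if {"day1", "day2"} <= set(by_day):
            ratios[group] = eth.habituation_ratio(day_occ["day1"], day_occ["day2"])
            shifts[group] = eth.group_transition_shift(
                day_tm["day1"], [o for _, o in day_occ["day1"].iterrows()],
                day_tm["day2"], [o for _, o in day_occ["day2"].iterrows()],
            )
    occ_path = outdir / "ethogram_occupancy.csv"
    pd.DataFrame(occ_rows).to_csv(occ_path, index=False)
    manifest.artifacts["ethogram/occupancy"] = str(occ_path)
    if ratios:
        ratio_path = outdir / "ethogram_habituation_ratios.csv"
        pd.DataFrame(ratios).to_csv(ratio_path)
        manifest.artifacts["ethogram/habituation_ratios"] = str(ratio_path)
    for group, shift in shifts.items():
        path = outdir / f"ethogram_transition_shift_{group}.csv"
        shift.to_csv(path)
        manifest.artifacts[f"ethogram/transition_shift/{group}"] = str(path)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def generate_report(manifest: RunManifest) -> str:
    """Markdown summary of a run; missing artifacts yield absent sections."""
    lines = [
        "# fosnet run report",
        "",
        f"- config hash: `{manifest.config_hash}`",
        f"- master seed: {manifest.seed}",
        f"- version: {manifest.version}",
        "",
    ]
    if manifest.failed_stage:
        lines.append(f"**Partial run: stage `{manifest.failed_stage}` failed.**\n")
    for key, path in sorted(manifest.artifacts.items()):
        if key.startswith("bwas/"):
            name = key.split("/", 1)[1]
            lines.append(f"## BWAS: {name}\n")
            try:
                frame = pd.read_csv(path, index_col=0)
            except OSError:
                lines.append("*(artifact missing)*\n")
                continue
            ok = frame[frame["status"] == "ok"]
            sig = ok[ok["p"] < 0.05].sort_values("p")
            lines.append(f"{len(ok)} regions analyzed, "
                         f"{len(sig)} significant at p < 0.05.\n")
            if len(sig):
                cols = ["beta1", "fold", "z", "p", "q"]
                lines.append(sig[cols].round(4).to_markdown())
                lines.append("")
            else:
                lines.append("No regions reached significance.\n")
        elif key.startswith("network/") and key.endswith("/threshold"):
            name = key.split("/")[1]
            lines.append(f"## Network threshold: {name}\n")
            try:
                sel = json.load(open(path))
            except OSError:
                lines.append("*(artifact missing)*\n")
                continue
            lines.append(
                f"rho_threshold = {sel['rho_threshold']}, "
                f"P_threshold = {sel['p_threshold']}, pi0 = {sel['pi0']:.3f}, "
                f"C = {sel['n_edges']} edges, FDR = {sel['fdr']}\n"
            )
        elif key == "ethogram/habituation_ratios":
            lines.append("## Habituation ratios (day 2 / day 1)\n")
            try:
                lines.append(pd.read_csv(path, index_col=0).round(3).to_markdown())
                lines.append("")
            except OSError:
                lines.append("*(artifact missing)*\n")
    if manifest.warnings:
        lines.append("## Warnings\n")
        lines += [f"- {w}" for w in manifest.warnings]
    return "\n".join(lines) + "\n"
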