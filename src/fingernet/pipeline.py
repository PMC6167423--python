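"""End-to-end orchestration: config -> preprocessed spectra -> OSC-filtered
PLS-DA models -> fingerprints -> metabolic sub-networks -> set algebra.

A single YAML config describes inputs (or synthetic-generation
parameters), preprocessing and chemometric options, the comparisons to
run, and pairs of fingerprints whose sub-networks are intersected
(common machinery) and subtracted (exposure-specific machinery).  All
randomness derives from one master seed via stable hashing, so identical
config + seed reproduces identical numerical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import yaml

from . import network as netmod
from . import synth
from .chemometrics import PLSDA, osc_filter, pca_screen
from .design import StudyDesign, default_design
from .fingerprint import (
    Fingerprint,
    aggregate_fingerprints,
    annotate_bins,
    load_shift_table,
    select_discriminant_bins,
)
from .preprocess import SpectraMatrix, normalize_total_area, scale

__all__ = ["PipelineConfig", "PipelineError", "load_config", "validate_config",
           "run_pipeline"]

log = logging.getLogger("fingernet")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name in the message."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (< 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
_DEFAULTS = {
    "preprocess": {
        "normalize": True,
        "scaling": "center_pareto",
        "screen_outliers": True,
        "outlier_alpha": 0.05,
        "exclude_outliers": False,
    },
    "chemometrics": {
        "folds": 7,
        "n_perm": 200,
        "n_osc": 1,
        "vip_threshold": 1.5,
        "alpha": 0.05,
        "max_components": 10,
        "tol_ppm": 0.02,
    },
    "network": {
        "weight_scheme": "degree_squared",
        "side_compounds": "default",
        "mapping": "default",
    },
}


@dataclass
class PipelineConfig:
    raw: dict
    seed: int
    output_dir: str
    synth: dict | None
    inputs: dict | None
    preprocess: dict
    chemometrics: dict
    network: dict
    comparisons: list
    pairs: list
    plots: bool = True

    @property
    def config_hash(self) -> str:
        # output_dir excluded: the same analysis into two directories is the
        # same analysis
        raw = {k: v for k, v in self.raw.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    def merged(section: str) -> dict:
        out = dict(_DEFAULTS.get(section, {}))
        out.update(raw.get(section) or {})
        return out

    return PipelineConfig(
        raw=raw,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "fingernet_out")),
        synth=raw.get("synth"),
        inputs=raw.get("inputs"),
        preprocess=merged("preprocess"),
        chemometrics=merged("chemometrics"),
        network=merged("network"),
        comparisons=raw.get("comparisons") or [],
        pairs=raw.get("pairs") or [],
        plots=bool(raw.get("plots", True)),
    )


def validate_config(path_or_dict) -> list[str]:
    """Collect every config problem; an empty list means valid."""
    errors: list[str] = []
    try:
        if isinstance(path_or_dict, dict):
            cfg = config_from_dict(path_or_dict)
        else:
            cfg = load_config(path_or_dict)
    except Exception as exc:  # unreadable / unparseable
        return [f"cannot read config: {exc}"]

    ch = cfg.chemometrics
    if ch["folds"] < 2:
        errors.append("chemometrics.folds must be >= 2")
    if ch["n_perm"] < 1:
        errors.append("chemometrics.n_perm must be >= 1")
    if ch["n_osc"] < 0:
        errors.append("chemometrics.n_osc must be >= 0")
    if ch["vip_threshold"] <= 0:
        errors.append("chemometrics.vip_threshold must be > 0")
    if not 0 < ch["alpha"] < 1:
        errors.append("chemometrics.alpha must be in (0, 1)")
    if ch["max_components"] < 1:
        errors.append("chemometrics.max_components must be >= 1")
    if cfg.preprocess["scaling"] not in ("center", "pareto", "center_pareto", "none"):
        errors.append(f"unknown preprocess.scaling {cfg.preprocess['scaling']!r}")
    if cfg.network["weight_scheme"] not in netmod.WEIGHT_SCHEMES:
        errors.append(f"unknown network.weight_scheme {cfg.network['weight_scheme']!r}")
    if cfg.synth is None and cfg.inputs is None:
        errors.append("either a synth block or an inputs block is required")
    if cfg.inputs is not None:
        for key in ("spectra", "design"):
            p = cfg.inputs.get(key)
            if not p:
                errors.append(f"inputs.{key} is required")
            elif not FsPath(p).exists():
                errors.append(f"inputs.{key} file not found: {p}")

    design = None
    try:
        design = _resolve_design(cfg)
    except Exception as exc:
        errors.append(f"cannot resolve the sample design: {exc}")
    if design is not None:
        known = set(design.groups)
        for comp in cfg.comparisons:
            cid = comp.get("id", "?")
            for g in comp.get("groups", []):
                if g not in known:
                    errors.append(f"comparison {cid!r}: unknown group {g!r}")
            if len(comp.get("groups", [])) < 2:
                errors.append(f"comparison {cid!r}: needs >= 2 groups")
    if not cfg.comparisons:
        errors.append("at least one comparison is required")
    for pair in cfg.pairs:
        if len(pair) != 2:
            errors.append(f"pair {pair!r} must name exactly 2 fingerprints")
    return errors


def _resolve_design(cfg: PipelineConfig) -> StudyDesign:
    if cfg.inputs is not None:
        return StudyDesign.read_tsv(cfg.inputs["design"])
    compounds = tuple((cfg.synth or {}).get("compounds", ["BPA"]))
    return default_design(compounds)


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------
def _acquire_spectra(cfg: PipelineConfig, design: StudyDesign) -> SpectraMatrix:
    if cfg.inputs is not None:
        return SpectraMatrix.read_tsv(cfg.inputs["spectra"])
    s = dict(cfg.synth or {})
    seed = stage_seed(cfg.seed, "simulate")
    kind = s.get("signatures", "demo")
    if kind == "shift_table":
        table = load_shift_table(s.get("shift_table", "combined"))
        sigs = synth.signatures_from_shift_table(
            table, design, effect=float(s.get("effect", 3.0)), seed=seed
        )
    else:
        sigs = synth.demo_signatures(
            design,
            n_signal_bins=int(s.get("n_signal_bins", 10)),
            effect=float(s.get("effect", 3.0)),
            seed=seed,
            dose_profile=s.get("dose_profile", "mixed"),
        )
    return synth.simulate_spectra(
        design,
        sigs,
        n_bins=int(s.get("n_bins", 200)),
        noise_sd=float(s.get("noise_sd", 1.0)),
        confounder_sd=float(s.get("confounder_sd", 2.0)),
        seed=seed,
    )


def _resolve_network(cfg: PipelineConfig) -> netmod.MetabolicNetwork:
    nc = cfg.network
    if nc.get("sbml"):
        net = netmod.read_sbml(nc["sbml"])
    elif nc.get("toy"):
        toy = nc["toy"]
        net = synth.generate_toy_network(
            n_metabolites=int(toy.get("n_metabolites", 30)),
            n_reactions=int(toy.get("n_reactions", 45)),
            n_compartments=int(toy.get("n_compartments", 2)),
            hub_degree=int(toy.get("hub_degree", 0)),
            seed=stage_seed(cfg.seed, "toy_network"),
        )
    else:
        # curated core-metabolism demo network; ids match the name mapping
        net = synth.demo_metabolic_network()
    return netmod.merge_compartments(net).network


def _scale_for_model(m: SpectraMatrix, scaling: str) -> np.ndarray:
    if scaling == "none":
        return m.intensities - m.intensities.mean(axis=0, keepdims=True)
    return scale(m, scaling).intensities


@dataclass
class ComparisonResult:
    comparison_id: str
    groups: list
    results: object  # PLSDAResults
    permutation: object  # PermutationResult | None
    fingerprints: list  # Fingerprint, joint first then per-dose
    outliers: list


def _run_comparison(cfg: PipelineConfig, comp: dict, spectra: SpectraMatrix,
                    design: StudyDesign, shift_table) -> ComparisonResult:
    ch = cfg.chemometrics
    cid = comp["id"]
    sub_design, rows = design.subset(comp["groups"])
    sub = SpectraMatrix(
        spectra.intensities[rows],
        spectra.ppm_centers,
        spectra.bin_width,
        tuple(spectra.sample_ids[i] for i in rows),
        spectra.scaling_state,
    )
    X = _scale_for_model(sub, cfg.preprocess["scaling"])

    outliers: list[str] = []
    if cfg.preprocess["screen_outliers"]:
        screen = pca_screen(
            X - X.mean(axis=0, keepdims=True) if cfg.preprocess["scaling"] == "pareto" else X,
            n_components=2,
            alpha=cfg.preprocess["outlier_alpha"],
        )
        outliers = [sub_design.sample_ids[i] for i in np.flatnonzero(screen.outlier_flags)]
        if outliers and cfg.preprocess["exclude_outliers"]:
            keep = ~screen.outlier_flags
            tab = sub_design.table.loc[keep].reset_index(drop=True)
            sub_design = StudyDesign(tab, sub_design.control_group)
            sub = SpectraMatrix(
                sub.intensities[keep], sub.ppm_centers, sub.bin_width,
                tuple(np.array(sub.sample_ids)[keep]), sub.scaling_state,
            )
            X = _scale_for_model(sub, cfg.preprocess["scaling"])
            log.info("%s: excluded outlier(s) %s", cid, outliers)

    if ch["n_osc"] > 0:
        X = osc_filter(X, sub_design, n_osc=ch["n_osc"]).filtered_X

    seed = stage_seed(cfg.seed, f"fit:{cid}")
    res = PLSDA(X, sub_design).fit(
        n_components=comp.get("n_components"),
        max_components=ch["max_components"],
        cv_folds=ch["folds"],
        seed=seed,
    )
    perm = None
    if ch["n_perm"] > 0:
        perm = res.permutation_test(n_perm=ch["n_perm"], seed=stage_seed(cfg.seed, f"perm:{cid}"))

    vip = res.vip()
    filtered = SpectraMatrix(X, sub.ppm_centers, sub.bin_width, sub.sample_ids,
                             "centered_pareto")
    fingerprints = []
    joint_bins = select_discriminant_bins(
        vip, filtered, sub_design, ch["vip_threshold"], ch["alpha"]
    )
    fingerprints.append(
        annotate_bins(joint_bins, shift_table, ch["tol_ppm"], cid,
                      ch["vip_threshold"], ch["alpha"])
    )
    if comp.get("per_dose", True):
        for g in sub_design.groups:
            if g == sub_design.control_group:
                continue
            pair_design, pair_rows = sub_design.subset([sub_design.control_group, g])
            pair_m = SpectraMatrix(
                X[pair_rows], sub.ppm_centers, sub.bin_width,
                tuple(sub.sample_ids[i] for i in pair_rows), "centered_pareto",
            )
            bins = select_discriminant_bins(
                vip, pair_m, pair_design, ch["vip_threshold"], ch["alpha"]
            )
            fingerprints.append(
                annotate_bins(bins, shift_table, ch["tol_ppm"], f"{g}_vs_control",
                              ch["vip_threshold"], ch["alpha"])
            )
    return ComparisonResult(cid, comp["groups"], res, perm, fingerprints, outliers)


def _subnetworks(cfg: PipelineConfig, fingerprints: dict, net) -> tuple[dict, dict, list]:
    """Map fingerprints to seeds and extract one sub-network each."""
    nc = cfg.network
    mapping = (
        netmod.load_name_mapping()
        if nc["mapping"] == "default"
        else netmod.load_name_mapping(nc["mapping"])
    )
    side_ids = (
        netmod.default_side_compounds()
        if nc["side_compounds"] == "default"
        else netmod.default_side_compounds(nc["side_compounds"])
    )
    side = netmod.resolve_side_compounds(net, side_ids)

    seeds_by_fp: dict[str, set] = {}
    notes: list[str] = []
    all_seeds: set = set()
    for fid, fp in fingerprints.items():
        seeds, unmapped = netmod.map_fingerprint_to_network(fp, mapping)
        seeds_by_fp[fid] = seeds
        all_seeds |= seeds
        if unmapped:
            notes.append(f"{fid}: unmapped metabolite name(s) {unmapped}")
    collisions = side & all_seeds
    if collisions:
        # fingerprint metabolites outrank their side-compound listing
        notes.append(
            f"seed/side-compound collision(s) kept as seeds: {sorted(collisions)}"
        )
        side -= collisions

    graph = netmod.build_compound_graph(net, side, nc["weight_scheme"])
    subnets: dict[str, netmod.SubNetwork] = {}
    for fid, seeds in seeds_by_fp.items():
        if len(seeds & set(graph.metabolite_nodes)) < 2:
            notes.append(f"{fid}: fewer than 2 mappable seeds; no sub-network")
            continue
        subnets[fid] = netmod.extract_subnetwork(graph, seeds)
    return subnets, seeds_by_fp, notes


# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig | dict | str) -> dict:
    """Run every stage; writes outputs under ``config.output_dir`` and
    returns the run report (also written as ``report.json``).

    Any stage error aborts with the stage name; files written so far in
    this run are removed.
    """
    if isinstance(config, (str, FsPath)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = config_from_dict(config)
    problems = validate_config(config.raw)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))

    out = FsPath(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[FsPath] = []

    def path_for(*parts) -> FsPath:
        p = out.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        written.append(p)
        return p

    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "comparisons": {},
        "notes": [],
    }
    stage = "setup"
    t0 = time.time()
    try:
        stage = "design"
        design = _resolve_design(config)
        design.write_tsv(path_for("design.tsv"))

        stage = "spectra"
        spectra = _acquire_spectra(config, design)
        spectra.write_tsv(path_for("spectra_raw.tsv"))
        if config.preprocess["normalize"] and spectra.scaling_state == "raw":
            spectra = normalize_total_area(spectra)

        stage = "shift_table"
        tbl = config.chemometrics.get("shift_table", "combined")
        shift_table = load_shift_table(tbl) if isinstance(tbl, str) else tbl

        fingerprints: dict[str, Fingerprint] = {}
        for comp in config.comparisons:
            stage = f"comparison:{comp.get('id', '?')}"
            cres = _run_comparison(config, comp, spectra, design, shift_table)
            cdir = cres.comparison_id
            summary = cres.results.to_dict()
            if cres.permutation is not None:
                summary["permutation_p_q2"] = cres.permutation.empirical_p_q2
            summary["outliers_flagged"] = cres.outliers
            summary["fingerprints"] = {
                fp.comparison_id: fp.metabolites for fp in cres.fingerprints
            }
            report["comparisons"][cres.comparison_id] = summary
            with open(path_for(cdir, "model.json"), "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            np.savetxt(
                path_for(cdir, "scores.tsv"),
                cres.results.scores,
                delimiter="\t",
                header="\t".join(
                    f"t{a + 1}" for a in range(cres.results.n_components)
                ),
                comments="",
            )
            for fp in cres.fingerprints:
                fp.to_dataframe().to_csv(
                    path_for(cdir, f"fingerprint_{fp.comparison_id}.tsv"),
                    sep="\t", index=False,
                )
                fingerprints[fp.comparison_id] = fp
            if config.plots:
                stage = f"plot:{cres.comparison_id}"
                from .plotting import score_plot

                sub_design, _ = design.subset(comp["groups"])
                if cres.outliers and config.preprocess["exclude_outliers"]:
                    keep = ~sub_design.table["sample_id"].isin(cres.outliers)
                    sub_design = StudyDesign(
                        sub_design.table.loc[keep].reset_index(drop=True),
                        sub_design.control_group,
                    )
                score_plot(
                    cres.results, sub_design,
                    path=path_for(cdir, "score_plot.png"),
                    title=cres.comparison_id,
                )

        stage = "fingerprint_table"
        if fingerprints:
            table = aggregate_fingerprints(list(fingerprints.values()))
            table.write_tsv(path_for("fingerprint_table.tsv"))
            report["n_unique_metabolites"] = table.n_unique_metabolites

        stage = "network"
        net = _resolve_network(config)
        subnets, seeds_by_fp, notes = _subnetworks(config, fingerprints, net)
        report["notes"].extend(notes)
        report["subnetworks"] = {}
        for fid, sn in subnets.items():
            report["subnetworks"][fid] = {
                "n_metabolites": len(sn.metabolites),
                "n_reactions": len(sn.reactions),
                "seeds": sorted(sn.seeds),
                "unreachable_pairs": [list(p) for p in sn.unreachable_pairs],
            }
            netmod.export_subnetwork(sn, path_for("network", f"{fid}.sif"), "sif")
            netmod.export_subnetwork(
                sn, path_for("network", f"{fid}.graphml"), "graphml"
            )

        stage = "pairs"
        report["pairs"] = {}
        for a, b in config.pairs:
            if a not in subnets or b not in subnets:
                report["notes"].append(f"pair ({a}, {b}): missing sub-network")
                continue
            common = netmod.subnetwork_algebra(subnets[a], subnets[b], "intersect")
            specific = netmod.subnetwork_algebra(subnets[a], subnets[b], "difference")
            key = f"{a}__{b}"
            report["pairs"][key] = {
                "common_metabolites": sorted(common.metabolites),
                "common_reactions": sorted(common.reactions),
                "specific_metabolites": sorted(specific.metabolites),
                "specific_reactions": sorted(specific.reactions),
            }
            if not common.is_empty():
                netmod.export_subnetwork(
                    common, path_for("network", f"common_{key}.sif"), "sif"
                )
            if not specific.is_empty():
                netmod.export_subnetwork(
                    specific, path_for("network", f"specific_{key}.sif"), "sif"
                )

        stage = "report"
        # wall time only to the log: report.json stays byte-identical across reruns
        with open(path_for("report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("pipeline finished in %.1fs", time.time() - t0)
        return report
    except Exception as exc:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
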