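"""Orchestrate the full divergence analysis from a single config file.

Stages: ``seq`` (read/concatenate/collapse), ``popgen`` (diversity,
between-population distance, AMOVA, neutrality), ``demography`` (mismatch
fit + SSD bootstrap, unit conversions), ``network`` (statistical
parsimony), ``niche`` (background divergence test) and ``morph``
(Kruskal-Wallis).  Each stage is skippable; skipping one never changes
the results of stages that do run.

One master seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence([master, stage_index])`` with fixed stage
indices (popgen=1, demography=2, niche=4), so individual stages are
reproducible in isolation.  Two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import demography as demog
from . import haplonet, niche, popstats, seqio

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline"]

_STAGE_INDEX = {"seq": 0, "popgen": 1, "demography": 2, "network": 3, "niche": 4, "morph": 5}
_ALL_STAGES = tuple(_STAGE_INDEX)


@dataclass
class RunConfig:
    """Flat key-value run configuration (YAML-loadable)."""

    seed: int = 1
    loci: list[dict] = field(default_factory=list)       # [{name, path}]
    metadata: str | None = None
    occurrences: str | None = None
    rasters_dir: str | None = None
    raster_priority: list[str] | None = None
    morphology: str | None = None
    site_policy: str = "complete_deletion"
    n_perm: int = 16000
    n_boot: int = 1000
    alpha_net: float = 0.95
    corr_threshold: float = 0.80
    n_background: int = 1000
    n_jack: int = 1000
    jack_frac: float = 0.75
    n_axes: int = 3
    rates: dict[str, float] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    a: float = 2.5
    s: float = 0.35
    ima: dict[str, float] | None = None
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.seed), _STAGE_INDEX[stage]])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def validate_config(cfg: RunConfig) -> None:
    """Check referenced paths and parameter bounds before any compute."""
    bad_stages = set(cfg.stages) - set(_ALL_STAGES)
    if bad_stages:
        raise ValueError(f"unknown stages: {sorted(bad_stages)}")
    needs_seq = {"seq", "popgen", "demography", "network"} & set(cfg.stages)
    if needs_seq:
        if not cfg.loci:
            raise ValueError("sequence stages requested but no loci configured")
        for locus in cfg.loci:
            if not Path(locus["path"]).exists():
                raise FileNotFoundError(f"locus FASTA missing: {locus['path']}")
        if not cfg.metadata or not Path(cfg.metadata).exists():
            raise FileNotFoundError(f"metadata TSV missing: {cfg.metadata}")
    if "niche" in cfg.stages:
        if not cfg.occurrences or not Path(cfg.occurrences).exists():
            raise FileNotFoundError(f"occurrence CSV missing: {cfg.occurrences}")
        if not cfg.rasters_dir or not Path(cfg.rasters_dir).is_dir():
            raise FileNotFoundError(f"raster directory missing: {cfg.rasters_dir}")
    if "morph" in cfg.stages:
        if not cfg.morphology or not Path(cfg.morphology).exists():
            raise FileNotFoundError(f"morphology TSV missing: {cfg.morphology}")
    if not 0 < cfg.alpha_net < 1:
        raise ValueError("alpha_net must be in (0, 1)")
    if not 0 < cfg.jack_frac <= 1:
        raise ValueError("jack_frac must be in (0, 1]")
    if cfg.site_policy not in {"complete_deletion", "pairwise_deletion"}:
        raise ValueError(f"unknown site policy {cfg.site_policy!r}")


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    """Stable rounding so reports are byte-identical across runs."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and write the report bundle.

    Outputs under ``outdir``: ``report.json`` (versioned, schema-validated),
    ``manifest.json`` (seeds, parameters), plus ``network.graphml`` and
    per-group mismatch TSVs when those stages run.  Any stage failure
    aborts with the stage name; partial outputs are kept next to a
    ``FAILED`` marker file.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"report_version": 1, "stages_run": []}
    current = "setup"
    try:
        aln = meta = None
        if {"seq", "popgen", "demography", "network"} & set(cfg.stages):
            current = "seq"
            alns = [seqio.read_alignment(l["path"], l["name"]) for l in cfg.loci]
            aln = seqio.concatenate(alns)
            meta = seqio.read_metadata(cfg.metadata)
            table = seqio.collapse_haplotypes(aln, meta, cfg.site_policy)
            table.write_tsv(outdir / "haplotypes.tsv", outdir / "assignment.tsv")
            report["seq"] = {
                "n_samples": aln.n,
                "length": aln.length,
                "loci": [
                    {"name": nm, "start": s, "end": e} for nm, s, e in aln.locus_bounds
                ],
                "n_haplotypes": table.k,
                "populations": list(table.populations),
                "shared_haplotypes": int(np.sum((table.counts > 0).sum(axis=1) > 1)),
            }
            report["stages_run"].append("seq")

        if "popgen" in cfg.stages:
            current = "popgen"
            pop_of = {m.sample_id: m.population for m in meta}
            div = popstats.population_diversity(aln, meta, cfg.site_policy)
            dm = seqio.pairwise_distances(aln, "jukes_cantor", cfg.site_policy)
            dm.write_tsv(outdir / "distances_jc.tsv")
            am = popstats.amova(
                dm, pop_of, n_perm=cfg.n_perm, seed=cfg.stage_seed("popgen")
            )
            pops = sorted({m.population for m in meta})
            pairs = []
            for i in range(len(pops)):
                for j in range(i + 1, len(pops)):
                    d = popstats.between_pop_distance(
                        aln, meta, pops[i], pops[j], cfg.site_policy
                    )
                    pairs.append(
                        {
                            "pop_x": d.pop_x, "pop_y": d.pop_y,
                            "dxy_percent": d.dxy_percent, "da_percent": d.da_percent,
                        }
                    )
            neut = {}
            groups = {p: [m.sample_id for m in meta if m.population == p] for p in pops}
            groups["overall"] = [m.sample_id for m in meta]
            for name, ids in groups.items():
                if len(ids) < 2:
                    continue
                r = popstats.neutrality(aln.subset(ids), cfg.site_policy)
                neut[name] = {
                    "n": r.n, "S": r.S, "k": r.k, "theta_pi": r.theta_pi,
                    "D": None if np.isnan(r.D) else r.D,
                    "Fs": None if np.isnan(r.Fs) else r.Fs,
                }
            report["popgen"] = {
                "diversity": [
                    {
                        "population": d.population, "n": d.n, "k": d.k,
                        "h": d.h, "h_sd": d.h_sd, "pi": d.pi, "pi_sd": d.pi_sd,
                    }
                    for d in div
                ],
                "between": pairs,
                "amova": {
                    "phi": am.phi, "p": am.p, "df_among": am.df_among,
                    "df_within": am.df_within, "sigma_among": am.sigma_among,
                    "sigma_within": am.sigma_within, "n_perm": am.n_perm,
                },
                "neutrality": neut,
            }
            report["stages_run"].append("popgen")

        if "demography" in cfg.stages:
            current = "demography"
            pops = sorted({m.population for m in meta})
            groups = {p: [m.sample_id for m in meta if m.population == p] for p in pops}
            groups["overall"] = [m.sample_id for m in meta]
            fits = {}
            seed0 = cfg.stage_seed("demography")
            for gi, (name, ids) in enumerate(sorted(groups.items())):
                if len(ids) < 2:
                    continue
                sub = aln.subset(ids)
                hist = demog.mismatch_histogram(sub, cfg.site_policy)
                fit = demog.fit_sudden_expansion(hist, n=sub.n)
                fit = demog.ssd_bootstrap(
                    fit, n=sub.n, L=sub.length, n_boot=cfg.n_boot,
                    seed=seed0 + gi, site_policy=cfg.site_policy,
                )
                exp = demog.expected_mismatch(
                    len(hist.counts) - 1, fit.tau, fit.theta0, fit.theta1
                )
                pd.DataFrame(
                    {
                        "j": np.arange(len(hist.counts)),
                        "observed": hist.frequencies,
                        "expected": exp,
                    }
                ).to_csv(outdir / f"mismatch_{name}.tsv", sep="\t", index=False)
                fits[name] = {
                    "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
                    "SSD": fit.SSD, "p_ssd": fit.p_ssd, "n_boot": fit.n_boot,
                    "expansion_rejected": bool(fit.p_ssd is not None and fit.p_ssd <= 0.05),
                }
            dem_block: dict[str, Any] = {"mismatch": fits}
            dem_block["generation_time"] = demog.generation_time(cfg.a, cfg.s)
            if cfg.ima and cfg.rates and cfg.lengths:
                scaling = demog.DemogScaling(
                    a=cfg.a, s=cfg.s, rates=cfg.rates, lengths=cfg.lengths
                )
                conv = demog.convert_ima(scaling=scaling, **cfg.ima)
                dem_block["ima"] = {
                    "N_a": conv.N_a, "N_1": conv.N_1, "N_2": conv.N_2,
                    "t_years": conv.t_years, "Nm_12": conv.Nm_12,
                    "Nm_21": conv.Nm_21, "aggregation": conv.aggregation,
                }
            report["demography"] = dem_block
            report["stages_run"].append("demography")

        if "network" in cfg.stages:
            current = "network"
            table = seqio.collapse_haplotypes(aln, meta, cfg.site_policy)
            L_net = len(table.haplotypes[0]) if table.haplotypes else aln.length
            limit = haplonet.parsimony_connection_limit(L_net, cfg.alpha_net)
            net = haplonet.build_network(table, limit)
            net.write_graphml(outdir / "network.graphml")
            net.edge_list_frame().to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
            net.population_table().to_csv(outdir / "network_pies.tsv", sep="\t", index=False)
            report["network"] = {
                "connection_limit": limit,
                "n_observed": len(net.observed_nodes),
                "n_inferred": len(net.inferred_nodes),
                "n_edges": net.graph.number_of_edges(),
                "n_components": len(net.components),
            }
            report["stages_run"].append("network")

        if "niche" in cfg.stages:
            current = "niche"
            occ = niche.read_occurrences(cfg.occurrences)
            if len(occ) != 2:
                raise ValueError("niche stage expects exactly two lineages")
            stack = niche.RasterStack.from_directory(cfg.rasters_dir)
            (lin_a, pts_a), (lin_b, pts_b) = sorted(occ.items())
            occ_a = niche.extract_climate(pts_a, stack, lin_a)
            occ_b = niche.extract_climate(pts_b, stack, lin_b)
            pooled = pd.concat([occ_a.climate, occ_b.climate], ignore_index=True)
            kept, dropped = niche.filter_correlated(
                pooled, cfg.corr_threshold, cfg.raster_priority
            )
            seed_n = cfg.stage_seed("niche")
            bg_a = niche.sample_background(
                niche.minimum_convex_polygon(occ_a.points), stack,
                cfg.n_background, seed=seed_n,
            )[kept]
            bg_b = niche.sample_background(
                niche.minimum_convex_polygon(occ_b.points), stack,
                cfg.n_background, seed=seed_n + 1,
            )[kept]
            axes = niche.pca_niche(pd.concat([bg_a, bg_b], ignore_index=True))
            result = niche.background_divergence_test(
                axes.transform(occ_a.climate[kept]),
                axes.transform(occ_b.climate[kept]),
                axes.transform(bg_a),
                axes.transform(bg_b),
                axes=axes,
                n_axes=min(cfg.n_axes, len(kept)),
                n_jack=cfg.n_jack,
                frac=cfg.jack_frac,
                seed=seed_n + 2,
            )
            result.to_frame().to_csv(outdir / "niche_test.tsv", sep="\t", index=False)
            report["niche"] = {
                "lineages": [lin_a, lin_b],
                "kept_variables": kept,
                "dropped_pairs": [
                    {"kept": k, "dropped": d, "r": r} for k, d, r in dropped
                ],
                "variance_explained": result.variance_explained.tolist(),
                "axes": [
                    {
                        "axis": result.axes[i],
                        "observed": result.observed_diff[i],
                        "background": result.background_diff[i],
                        "null_lo": result.null_lo[i],
                        "null_hi": result.null_hi[i],
                        "verdict": result.verdict[i],
                    }
                    for i in range(len(result.axes))
                ],
            }
            report["stages_run"].append("niche")

        if "morph" in cfg.stages:
            current = "morph"
            df = pd.read_csv(cfg.morphology, sep="\t")
            if "population" not in df.columns:
                raise ValueError("morphology TSV needs a 'population' column")
            traits = [c for c in df.columns if c not in {"population", "sample_id", "sex"}]
            morph = {}
            for trait in traits:
                groups = [
                    g[trait].dropna().to_numpy()
                    for _, g in df.groupby("population", sort=True)
                ]
                H, pval = popstats.kruskal_wallis(groups)
                morph[trait] = {"H": H, "p": pval}
            report["morph"] = morph
            report["stages_run"].append("morph")

    except Exception as err:
        (outdir / "FAILED").write_text(f"stage {current}: {err}\n")
        raise RuntimeError(f"pipeline failed in stage {current!r}: {err}") from err

    report = _round_floats(report)
    validate_report(report)
    manifest = {
        "master_seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in cfg.stages},
        "parameters": {
            "site_policy": cfg.site_policy, "n_perm": cfg.n_perm,
            "n_boot": cfg.n_boot, "alpha_net": cfg.alpha_net,
            "corr_threshold": cfg.corr_threshold,
            "n_background": cfg.n_background, "n_jack": cfg.n_jack,
            "jack_frac": cfg.jack_frac, "a": cfg.a, "s": cfg.s,
        },
        "stages": list(cfg.stages),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _load_schema() -> dict:
    with resources.files("popdiv").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: Mapping[str, Any]) -> None:
    """Validate the report against the bundled structural schema
    (required keys and JSON types, checked recursively)."""
    schema = _load_schema()
    _check(report, schema, "report")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(obj: Any, schema: Mapping[str, Any], where: str) -> None:
    t = schema.get("type")
    if t:
        if obj is None and schema.get("nullable"):
            return
        if not isinstance(obj, _TYPES[t]) or (
            t in {"integer", "number"} and isinstance(obj, bool)
        ):
            raise ValueError(f"{where}: expected {t}, got {type(obj).__name__}")
    for key in schema.get("required", []):
        if key not in obj:
            raise ValueError(f"{where}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in obj:
            _check(obj[key], sub, f"{where}.{key}")
    items = schema.get("items")
    if items and isinstance(obj, list):
        for i, el in enumerate(obj):
            _check(el, items, f"{where}[{i}]")
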