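"""End-to-end orchestration: composition -> divergence -> cox2 -> URs ->
gene order -> phylogenetic patterns, emitting the table families of a
comparative F/M mitogenome study.

A single YAML config drives every threshold; the report carries a
provenance block (package version, seed, config hash, thresholds) and is
validated against the JSON schema shipped in ``duimito/data``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composition import codon_usage, composition_by_class
from .divergence import (cox2_mod_scan, global_align, ng86_dnds, p_distance,
                         p_distance_ungapped)
from .gene_order import compare_orders, gene_order_of
from .genome_io import MitoGenome, extract_gene_seq, read_genbank
from .phylo_patterns import SEP, SexTree, classify_patterns, nj_tree, pattern_summary
from .synthetic_data import SimConfig, simulate_clade, simulate_pair
from .ur_analysis import URConfig, characterize_urs, load_elements, ur_fraction

log = logging.getLogger("duimito")

__all__ = ["run_pipeline", "validate_report", "load_report_schema"]


class ConfigError(ValueError):
    pass


def load_report_schema() -> dict:
    with resources.files("duimito.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None, path: str = "$") -> None:
    """Minimal structural validation (type + required keys, recursive)."""
    schema = schema if schema is not None else load_report_schema()
    types = schema.get("type")
    if types is not None:
        allowed = types if isinstance(types, list) else [types]
        py = {"object": dict, "array": list, "string": str,
              "number": (int, float), "boolean": bool, "null": type(None)}
        if not any(isinstance(report, py[t]) for t in allowed):
            raise ValueError(f"{path}: expected {allowed}, got {type(report).__name__}")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            validate_report(item, schema["items"], f"{path}[{i}]")


def _load_genomes(cfg: dict) -> list[MitoGenome]:
    genomes: list[MitoGenome] = []
    if "genomes" in cfg:
        for entry in cfg["genomes"]:
            g = read_genbank(entry["path"], sex_field=entry.get("sex_field", "sex"))
            if entry.get("species"):
                g.species = entry["species"]
            if entry.get("sex"):
                g.sex_type = entry["sex"]
            genomes.append(g)
    elif "simulate" in cfg:
        sim = cfg["simulate"]
        seed = int(cfg.get("seed", 0))
        if sim.get("scenario", "pair") == "pair":
            sc = SimConfig(seed=seed,
                           nt_divergence=float(sim.get("divergence", 0.2)),
                           scale=float(sim.get("scale", 1.0)))
            f, m, _ = simulate_pair(sc)
            genomes = [f, m]
        else:
            genomes, _ = simulate_clade(sim["scenario"],
                                        int(sim.get("n_species", 3)), seed)
    else:
        raise ConfigError("config must list 'genomes' or a 'simulate' block")
    if not genomes:
        raise ConfigError("no genomes configured")
    return genomes


def _by_species(genomes: list[MitoGenome]) -> dict[str, dict[str, MitoGenome]]:
    out: dict[str, dict[str, MitoGenome]] = {}
    for g in genomes:
        out.setdefault(g.species, {})[g.sex_type] = g
    return out


def _whole_genome_p(a: MitoGenome, b: MitoGenome) -> float:
    if a.length == b.length:
        return p_distance_ungapped(a.sequence, b.sequence)
    al = global_align(a.sequence, b.sequence, mode="nt")
    rec = p_distance(al)
    return rec.p_nt if rec.p_nt is not None else float("nan")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the full comparative analysis and write TSV/JSON tables.

    Returns the report dict (also written to ``report.json``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not config:
        raise ConfigError("empty config")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ur_cfg = URConfig(**config.get("ur", {}))
    elements = load_elements(config.get("elements"))
    log.info("UR protocol thresholds: principal > %d nt, repeat weights %d/%d/%d "
             "min score %d, G-string %d-%d nt >= %.0f%% G, motif identity > %.0f%%",
             ur_cfg.min_principal, ur_cfg.trf_match, ur_cfg.trf_mismatch,
             ur_cfg.trf_indel, ur_cfg.trf_min_score, ur_cfg.gstring_min_len,
             ur_cfg.gstring_max_len, 100 * ur_cfg.gstring_min_fraction,
             100 * ur_cfg.motif_min_identity)
    genomes = _load_genomes(config)
    species_map = _by_species(genomes)

    genome_rows = [{"id": g.id, "species": g.species, "sex_type": g.sex_type,
                    "length": g.length} for g in genomes]
    comp_rows = []
    codon_rows = []
    for g in genomes:
        for rec in composition_by_class(g):
            comp_rows.append({"genome": g.id, "scope": rec.scope, "A": rec.a,
                              "T": rec.t, "G": rec.g, "C": rec.c,
                              "at_content": rec.at_content,
                              "at_skew": rec.at_skew, "gc_skew": rec.gc_skew})
        cu = codon_usage(g)
        for gc in cu.per_gene:
            codon_rows.append({"genome": g.id, "gene": gc.gene,
                               "start": gc.start_codon, "stop": gc.stop_codon,
                               "incomplete_stop": gc.incomplete_stop})

    div_rows, dnds_rows, cox2_rows, order_rows = [], [], [], []
    for sp, pair in sorted(species_map.items()):
        if "F" not in pair or "M" not in pair:
            log.info("species %s has a single sex type; F/M comparison skipped", sp)
            continue
        f, m = pair["F"], pair["M"]
        log.info("comparing F/M pair for %s", sp)
        div_rows.append({"species": sp, "scope": "whole_genome",
                         "p_nt": _whole_genome_p(f, m), "p_aa": None})
        f_genes = {ft.gene for ft in f.features}
        m_genes = {ft.gene for ft in m.features}
        for gene in sorted(f_genes & m_genes):
            fs, ms = extract_gene_seq(f, gene), extract_gene_seq(m, gene)
            cls = next(ft.cls for ft in f.features if ft.gene == gene)
            if cls == "PCG" and gene != "cox2":
                try:
                    al = global_align(fs, ms, mode="codon")
                except ValueError:
                    continue
                rec = p_distance(al, gene)
                div_rows.append({"species": sp, "scope": gene,
                                 "p_nt": rec.p_nt, "p_aa": None})
                dd = ng86_dnds(al, gene)
                dnds_rows.append({"species": sp, "gene": gene, "dN": dd.dn,
                                  "dS": dd.ds, "omega": dd.omega})
            elif cls == "rRNA":
                al = global_align(fs, ms, mode="nt")
                rec = p_distance(al, gene)
                div_rows.append({"species": sp, "scope": gene,
                                 "p_nt": rec.p_nt, "p_aa": None})
        if "cox2" in f_genes and "cox2" in m_genes:
            # the F copy serves as the unmodified reference for its own pair
            ref = config.get("reference_cox2") or extract_gene_seq(f, "cox2")
            reports = cox2_mod_scan(extract_gene_seq(f, "cox2"),
                                    extract_gene_seq(m, "cox2"), ref)
            for sex, rep in reports.items():
                cox2_rows.append({"species": sp, "genome": pair[sex].id,
                                  "kind": rep.kind, "length_nt": rep.length_nt,
                                  "length_codons": rep.length_codons,
                                  "tmh_in_modified_region": rep.tmh_in_modified_region})
        cmp_rep = compare_orders(gene_order_of(f), gene_order_of(m))
        order_rows.append({"species": sp,
                           "breakpoint_distance": cmp_rep.breakpoint_distance,
                           "transposed": ",".join(cmp_rep.transposed),
                           "duplicated_in_F": ",".join(cmp_rep.duplicated_in_a),
                           "duplicated_in_M": ",".join(cmp_rep.duplicated_in_b),
                           "absent_in_F": ",".join(cmp_rep.absent_in_a),
                           "absent_in_M": ",".join(cmp_rep.absent_in_b)})

    ur_rows, ur_details = [], []
    fractions = ur_fraction(genomes)
    for g in sorted(genomes, key=lambda x: (x.species, x.sex_type)):
        for r in characterize_urs(g, elements, ur_cfg):
            if not r.is_principal:
                continue
            other = sorted(r.fold.labels) if r.fold else []
            other += [f"({b})n" for b, _, _ in (r.homopolymers or [])]
            ur_rows.append({
                "genome": g.id, "flanks": f"{r.flank5}-{r.flank3}",
                "length": r.length,
                "at_percent": round(100 * r.at_content, 1) if r.at_content else None,
                "n_repeat_units": len(r.repeats or []),
                "copy_numbers": "+".join(str(h.copy_number) for h in (r.repeats or [])) or "/",
                "other": ", ".join(other) or "/",
                "is_lur": r.is_lur,
            })
            ur_details.append({"genome": g.id, "start": r.start, "end": r.end,
                               "repeats": [asdict(h) for h in (r.repeats or [])],
                               "g_strings": [asdict(h) for h in (r.g_strings or [])],
                               "motifs": [asdict(h) for h in (r.motifs or [])]})
        if not any(row["genome"] == g.id for row in ur_rows):
            log.info("genome %s has no principal UR", g.id)

    patterns: dict = {}
    tree_cfg = config.get("tree")
    outgroup = config.get("outgroup")
    st = None
    if tree_cfg:
        st = SexTree.from_newick(Path(tree_cfg).read_text(), outgroup=outgroup)
    else:
        both = [sp for sp, pair in species_map.items() if {"F", "M"} <= set(pair)]
        lengths = {g.length for g in genomes}
        if len(both) >= 2 and len(genomes) >= 4 and len(lengths) == 1:
            import numpy as np
            labels = [g.id if g.sex_type not in ("F", "M")
                      else f"{g.species}{SEP}{g.sex_type}" for g in genomes]
            n = len(genomes)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = p_distance_ungapped(
                        genomes[i].sequence, genomes[j].sequence)
            og = outgroup if outgroup in labels else None
            st = nj_tree(d, labels, outgroup=og)
    if st is not None and st.outgroup is not None:
        calls = classify_patterns(st)
        patterns = {"calls": [asdict(c) for c in calls],
                    "tally": pattern_summary(calls)}

    thresholds = asdict(ur_cfg)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    report = {
        "provenance": {"package": "duimito", "version": __version__,
                       "seed": config.get("seed"), "config_hash": cfg_hash,
                       "thresholds": thresholds},
        "genomes": genome_rows,
        "composition": comp_rows,
        "codon_usage": codon_rows,
        "divergence": div_rows,
        "dnds": dnds_rows,
        "cox2": cox2_rows,
        "ur_table": ur_rows,
        "ur_details": ur_details,
        "ur_fraction_percent": fractions,
        "gene_order": order_rows,
        "patterns": patterns,
    }
    validate_report(report)
    for name, rows in (("composition", comp_rows), ("codon_usage", codon_rows),
                       ("divergence", div_rows), ("dnds", dnds_rows),
                       ("cox2_mods", cox2_rows), ("ur_table", ur_rows),
                       ("gene_order", order_rows)):
        pd.DataFrame(rows).to_csv(out / f"{name}.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    log.info("report written to %s", out / "report.json")
    return report
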