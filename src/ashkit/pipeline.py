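"""Configuration-driven orchestration of the full analysis.

``run_all`` executes: optional synthetic-data generation, expression response
classification, peak-to-gene association (+ co-occupancy and the
target-vs-impaired cross-tabulation), chromatin-signature enrichment of the
impaired set, the DRB coverage analysis (RPKM -> 75th-percentile
normalization -> Δlog2 grouping -> RAR underrepresentation, plus a metagene
profile), and the qPCR/penetrance summaries.  Every output lands in the
configured directory with a JSON manifest of config and file digests, so a
rerun with the same seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as aio
from .association import AssociationRule, associate, co_occupancy, cross_tabulate
from .coverage import (
    drb_dlog2,
    group_by_response,
    metagene_profile,
    percentile75_normalize,
    region_rpkm_table,
    underrepresentation_test,
)
from .expression import (
    ExpressionTable,
    ResponseThresholds,
    classify_dysregulated,
    classify_impaired,
    classify_ra_responsive,
    summarize_fraction,
)
from .intervals import ValidationError
from .signatures import enrichment_vs_background, signature_table
from .statsqc import PhenotypeCounts, penetrance_table, summarize_qpcr_table
from .synth import SyntheticConfig, generate

__all__ = ["PipelineConfig", "RunManifest", "run_all", "load_config"]

log = logging.getLogger("ashkit.pipeline")

_TOP_KEYS = {
    "seed", "out_dir", "synth", "inputs", "thresholds", "association",
    "response_bins", "conditions", "qpcr_background",
}
_INPUT_KEYS = {
    "chrom_sizes", "genes_gtf", "genes_bed12", "expression", "ash1l_peaks",
    "rar_peaks", "signatures", "tracks", "qpcr", "phenotypes",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Path = Path("ashkit_out")
    synth: Optional[SyntheticConfig] = None
    inputs: Dict[str, object] = field(default_factory=dict)
    thresholds: ResponseThresholds = field(default_factory=ResponseThresholds)
    association_flank: int = 4000
    association_upstream: int = 20000
    response_edges: List[float] = field(default_factory=lambda: [-0.6, 0.6])
    conditions: Dict[str, str] = field(
        default_factory=lambda: {
            "wt": "WT", "wt_ra": "WT_RA", "mut": "dSET", "mut_ra": "dSET_RA"
        }
    )
    qpcr_background: float = 0.01


def load_config(path) -> PipelineConfig:
    """Parse and strictly validate a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", 0))
    if "out_dir" in raw:
        cfg.out_dir = Path(raw["out_dir"])
    if "synth" in raw and raw["synth"] is not None:
        synth_kwargs = dict(raw["synth"])
        synth_kwargs.setdefault("seed", cfg.seed)
        cfg.synth = SyntheticConfig(**synth_kwargs)
    if "inputs" in raw and raw["inputs"]:
        unknown = set(raw["inputs"]) - _INPUT_KEYS
        if unknown:
            raise ValidationError(f"unknown input keys: {sorted(unknown)}")
        cfg.inputs = dict(raw["inputs"])
    if "thresholds" in raw and raw["thresholds"]:
        cfg.thresholds = ResponseThresholds(**raw["thresholds"])
    assoc = raw.get("association") or {}
    cfg.association_flank = int(assoc.get("flank", cfg.association_flank))
    cfg.association_upstream = int(assoc.get("upstream", cfg.association_upstream))
    bins = raw.get("response_bins") or {}
    cfg.response_edges = list(bins.get("edges", cfg.response_edges))
    if "conditions" in raw and raw["conditions"]:
        cfg.conditions = dict(raw["conditions"])
    cfg.qpcr_background = float(raw.get("qpcr_background", cfg.qpcr_background))
    return cfg


@dataclass
class RunManifest:
    config: Dict
    version: str
    started: float
    finished: float = 0.0
    input_digests: Dict[str, str] = field(default_factory=dict)
    output_digests: Dict[str, str] = field(default_factory=dict)
    stage_log: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "started": self.started,
                "finished": self.finished,
                "input_digests": self.input_digests,
                "output_digests": self.output_digests,
                "stage_log": self.stage_log,
            },
            indent=2,
            default=str,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(inputs: Mapping[str, object], *keys: str) -> None:
    missing = [k for k in keys if k not in inputs]
    if missing:
        raise ValidationError(f"missing required inputs: {missing}")


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage; any stage error aborts with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: str(v) for k, v in vars(config).items() if k != "synth"},
        version=__version__,
        started=time.time(),
    )

    outputs: List[Path] = []

    def record(path: Path) -> Path:
        # digest computed after all stages have written their files
        outputs.append(path)
        return path

    inputs = dict(config.inputs)
    if config.synth is not None:
        log.info("stage synth: generating dataset (seed=%d)", config.synth.seed)
        truth = generate(config.synth, out / "inputs")
        for key, path in truth.paths.items():
            if key.startswith("track_"):
                inputs.setdefault("tracks", {})
                inputs["tracks"][key[len("track_"):]] = str(path.with_suffix(""))
            else:
                inputs.setdefault(key, str(path))
        manifest.stage_log.append("synth: generated %d genes" % len(truth.genes))

    _require(inputs, "chrom_sizes", "expression")
    for key, value in inputs.items():
        if key == "tracks":
            for tag, prefix in value.items():
                p = Path(str(prefix)).with_suffix(".bedgraph")
                if not p.exists():
                    raise ValidationError(f"missing track file {p}")
                manifest.input_digests[p.name] = _sha256(p)
        else:
            p = Path(str(value))
            if not p.exists():
                raise ValidationError(f"missing input file {p} (key {key!r})")
            manifest.input_digests[p.name] = _sha256(p)

    genome = aio.read_chrom_sizes(inputs["chrom_sizes"])
    if "genes_gtf" in inputs:
        genes = aio.read_gene_models_gtf(inputs["genes_gtf"], genome)
    elif "genes_bed12" in inputs:
        genes = aio.read_gene_models_bed12(inputs["genes_bed12"], genome)
    else:
        raise ValidationError("need genes_gtf or genes_bed12 input")
    universe = {g.gene_id for g in genes}
    log.info("loaded %d genes on %d chromosomes", len(genes), len(genome.chrom_sizes))

    # --- expression stage -------------------------------------------------
    table = ExpressionTable(aio.read_expression_table(inputs["expression"]))
    cond = config.conditions
    labels = classify_ra_responsive(
        table, cond["wt_ra"], cond["wt"], config.thresholds
    )
    labels = classify_impaired(
        table, cond["mut_ra"], cond["wt_ra"], labels, config.thresholds
    )
    down, up = classify_dysregulated(table, cond["mut"], cond["wt"], config.thresholds)
    n_resp = int(labels["responsive"].sum())
    n_imp = int(labels["impaired"].sum())
    manifest.stage_log.append(
        f"expression: {len(labels)} eligible, {n_resp} responsive, "
        f"{n_imp} impaired"
        + (
            f" ({summarize_fraction(n_imp, n_resp)}%)" if n_resp else ""
        )
        + f", {len(down)} down / {len(up)} up in undifferentiated mutant"
    )
    labels.to_csv(record(out / "expression_labels.tsv"), sep="\t",
                  index_label="gene_id")

    responsive_set = set(labels.index[labels["responsive"]])
    impaired_set = set(labels.index[labels["impaired"]])

    # --- association stage ------------------------------------------------
    ash1l_targets: set = set()
    rar_genes: set = set()
    if "ash1l_peaks" in inputs:
        ash1l = aio.read_bed(inputs["ash1l_peaks"], "Ash1l", genome)
        res = associate(
            genes, ash1l,
            AssociationRule("tss_window", flank=config.association_flank), genome,
        )
        ash1l_targets = res.associated_genes()
        pd.DataFrame(
            {
                "associated": pd.Series(res.flags),
                "peaks": pd.Series({k: ",".join(v) for k, v in res.peak_names.items()}),
            }
        ).to_csv(record(out / "associations_ash1l.tsv"), sep="\t",
                 index_label="gene_id")
    if "rar_peaks" in inputs:
        rar = aio.read_bed(inputs["rar_peaks"], "RAR", genome)
        res = associate(
            genes, rar,
            AssociationRule("upstream_and_body", upstream=config.association_upstream),
            genome,
        )
        rar_genes = res.associated_genes()
        pd.DataFrame(
            {
                "associated": pd.Series(res.flags),
                "peaks": pd.Series({k: ",".join(v) for k, v in res.peak_names.items()}),
            }
        ).to_csv(record(out / "associations_rar.tsv"), sep="\t", index_label="gene_id")
    if "ash1l_peaks" in inputs and "rar_peaks" in inputs and len(rar):
        frac = co_occupancy(rar, ash1l, max_gap=0)
        venn = cross_tabulate(
            ash1l_targets & universe, impaired_set & universe, universe
        )
        with open(out / "association_summary.json", "w") as fh:
            json.dump(
                {
                    "rar_ash1l_cooccupancy": frac,
                    "cross_tab_target_vs_impaired": {
                        "both": venn[0], "target_only": venn[1],
                        "impaired_only": venn[2], "neither": venn[3],
                    },
                },
                fh, indent=2,
            )
        record(out / "association_summary.json")
        manifest.stage_log.append(
            f"association: {len(ash1l_targets)} Ash1l targets, "
            f"{len(rar_genes)} RAR-associated, co-occupancy {frac:.3f}"
        )

    # --- signature enrichment stage --------------------------------------
    if "signatures" in inputs and impaired_set:
        sig = signature_table(aio.read_signature_labels(inputs["signatures"]))
        sig_universe = set(sig.index) & universe
        group = impaired_set & sig_universe
        if group:
            report = enrichment_vs_background(
                group, sig, sig_universe, group_label="impaired"
            )
            report.to_frame().to_csv(
                record(out / "enrichment_impaired.tsv"), sep="\t"
            )
            manifest.stage_log.append(
                "signatures: impaired-set enrichment written "
                f"(n={len(group)} vs universe {len(sig_universe)})"
            )

    # --- coverage stage ---------------------------------------------------
    tracks = {}
    for tag, prefix in (inputs.get("tracks") or {}).items():
        tracks[tag] = aio.read_track(prefix, genome)
    for mark in ("k36me3", "k36me2"):
        plus_tag, minus_tag = f"{mark}_plus", f"{mark}_minus"
        if plus_tag not in tracks or minus_tag not in tracks:
            continue
        plus = percentile75_normalize(region_rpkm_table(tracks[plus_tag], genes))
        minus = percentile75_normalize(region_rpkm_table(tracks[minus_tag], genes))
        d = drb_dlog2(plus, minus, pseudocount=config.thresholds.pseudocount)
        groups = group_by_response(d, edges=config.response_edges)
        df = pd.DataFrame({"dlog2": d, "group": groups})
        df.to_csv(record(out / f"drb_response_{mark}.tsv"), sep="\t",
                  index_label="gene_id")
        if rar_genes:
            flags = pd.Series(
                {g.gene_id: g.gene_id in rar_genes for g in genes}
            )
            report = underrepresentation_test(groups, flags)
            report.to_frame().to_csv(
                record(out / f"rar_representation_{mark}.tsv"), sep="\t"
            )
        profile = metagene_profile(tracks[minus_tag], genes, genome)
        prof_df = pd.DataFrame(
            {
                "column": profile.column_labels,
                "mean_count": profile.mean_profile(),
                "log2_ratio": profile.log2_ratio_profile(),
            }
        )
        prof_df.to_csv(record(out / f"metagene_{mark}_minus.tsv"), sep="\t",
                       index=False)
        with open(out / f"metagene_{mark}_minus.meta.json", "w") as fh:
            json.dump(profile.meta, fh, indent=2, default=str)
        record(out / f"metagene_{mark}_minus.meta.json")
        manifest.stage_log.append(
            f"coverage {mark}: groups "
            + ", ".join(f"{k}={v}" for k, v in groups.value_counts().items())
        )

    # --- small statistics stage ------------------------------------------
    if "qpcr" in inputs:
        qpcr = pd.read_csv(inputs["qpcr"], sep="\t")
        summarize_qpcr_table(qpcr, background=config.qpcr_background).to_csv(
            record(out / "qpcr_summary.tsv"), sep="\t", index=False
        )
        manifest.stage_log.append("qpcr: summarized")
    if "phenotypes" in inputs:
        ph = pd.read_csv(inputs["phenotypes"], sep="\t")
        affected: Dict[str, Dict[str, int]] = {}
        totals: Dict[str, int] = {}
        for _, row in ph.iterrows():
            affected.setdefault(row["genotype"], {})[row["phenotype"]] = int(
                row["affected"]
            )
            totals[row["genotype"]] = int(row["total"])
        penetrance_table(PhenotypeCounts(affected, totals)).to_csv(
            record(out / "penetrance.tsv"), sep="\t"
        )
        manifest.stage_log.append("phenotypes: penetrance tabulated")

    for path in outputs:
        manifest.output_digests[path.name] = _sha256(path)
    manifest.finished = time.time()
    with open(out / "manifest.json", "w") as fh:
        fh.write(manifest.to_json())
    return manifest
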