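"""End-to-end pipeline orchestration with a manifest of outputs.

Stages run in dependency order — redundancy collapse, sequence features
(ORF/CDS, SSR, lncRNA) and alternative-splicing calling on the non-redundant
set, expression quantification and differential expression, then the
co-expression network — writing plain-text tables into one output directory
and recording every file with a content checksum in ``manifest.json``.
Rerunning with the same config and inputs reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import as_caller, collapse, coexpression, quant_de, sequence_features as feats
from .synthetic_data import (
    SynthConfig,
    Transcript,
    generate_counts,
    generate_transcripts,
    read_fasta,
    write_counts,
    write_fasta,
    write_traits,
)

log = logging.getLogger("rhizoflow")


@dataclass
class PipelineConfig:
    out_dir: str = "rhizoflow_out"
    seed: int = 0
    # inputs; when absent and simulate=True they are generated
    transcripts_fasta: Optional[str] = None
    counts_tsv: Optional[str] = None
    traits_tsv: Optional[str] = None
    tf_table_tsv: Optional[str] = None
    simulate: bool = False
    synth: Optional[dict] = None  # SynthConfig field overrides for simulate
    # stage toggles
    run_collapse: bool = True
    run_features: bool = True
    run_as: bool = True
    run_quant: bool = True
    run_network: bool = True
    # stage parameters
    identity_threshold: float = 0.99
    min_orf_aa: int = 100
    lncrna_min_votes: int = 2
    min_hsp_len: int = 1000
    min_hsp_identity: float = 0.95
    max_overlap: int = 5
    min_gap: int = 100
    min_end_distance: int = 100
    fc_threshold: float = 4.0
    fdr_threshold: float = 0.01
    specific_top_n: int = 5
    specific_min_fpkm: float = 0.1
    specific_min_reps: int = 2
    network_min_fpkm: float = 1.0
    network_min_kme: float = 0.7
    network_min_module_size: int = 5
    network_tree_cut_height: float = 0.9

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run enabled stages; return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "params": asdict(config), "files": {}, "stages": []}

    def record(stage: str, path: Path) -> None:
        manifest["files"][path.name] = {"stage": stage, "sha256": _sha256(path)}

    # --- inputs ------------------------------------------------------------
    counts = traits = None
    if config.simulate:
        log.info("simulating inputs (seed=%d)", config.seed)
        scfg = SynthConfig(seed=config.seed, **(config.synth or {}))
        transcripts, truth = generate_transcripts(scfg)
        counts, traits = generate_counts(scfg, truth, transcripts)
        write_fasta(transcripts, out / "input_transcripts.fa")
        truth.to_json(out / "truth.json")
        write_counts(counts, out / "counts.tsv")
        write_traits(traits, out / "traits.tsv")
        for name in ("input_transcripts.fa", "truth.json", "counts.tsv", "traits.tsv"):
            record("simulate", out / name)
        manifest["stages"].append("simulate")
    else:
        if not config.transcripts_fasta:
            raise FileNotFoundError("transcripts_fasta is required unless simulate=true")
        transcripts = read_fasta(config.transcripts_fasta)
        if config.counts_tsv:
            counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        if config.traits_tsv:
            traits = pd.read_csv(config.traits_tsv, sep="\t", index_col=0)

    nr = transcripts
    # --- collapse ----------------------------------------------------------
    if config.run_collapse:
        log.info("collapse: %d transcripts", len(transcripts))
        clusters, nr = collapse.collapse_transcripts(
            transcripts, config.identity_threshold
        )
        write_fasta(nr, out / "nr.fa")
        collapse.write_clusters_tsv(clusters, out / "clusters.tsv")
        record("collapse", out / "nr.fa")
        record("collapse", out / "clusters.tsv")
        manifest["stages"].append("collapse")

    # --- sequence features -------------------------------------------------
    if config.run_features:
        log.info("features: ORFs/SSRs/lncRNA on %d transcripts", len(nr))
        all_orfs: dict[str, list] = {}
        for t in nr:
            all_orfs[t.id] = feats.find_orfs(t, min_aa=config.min_orf_aa)
        # self-trained hexamer table: complete ORFs as the coding set,
        # whole transcripts (position-free) as background
        coding_train = [
            feats.orf_nt_sequence(t, o)
            for t in nr
            for o in all_orfs[t.id]
            if o.completeness == "complete"
        ]
        table = None
        if coding_train:
            table = feats.train_hexamer_table(coding_train, [t.seq for t in nr])
            for t in nr:
                feats.score_orfs(t, all_orfs[t.id], table)
        orf_rows = [r for t in nr for r in feats.orfs_to_rows(all_orfs[t.id])]
        pd.DataFrame(
            orf_rows,
            columns=[
                "transcript_id", "strand", "frame", "start", "end",
                "completeness", "aa_length", "coding_score", "is_primary",
            ],
        ).to_csv(out / "orfs.tsv", sep="\t", index=False)
        ssr_rows = []
        for t in nr:
            ssr_rows.extend(feats.ssrs_to_rows(feats.find_ssrs(t)))
        pd.DataFrame(
            ssr_rows,
            columns=["ID", "SSR_nr", "type", "SSR", "size", "start", "end", "compound_group"],
        ).to_csv(out / "ssrs.tsv", sep="\t", index=False)
        lnc_rows = []
        for t in nr:
            c = feats.classify_lncrna(
                t, all_orfs[t.id], table, min_votes=config.lncrna_min_votes
            )
            lnc_rows.append(
                {
                    "transcript_id": c.transcript_id,
                    "length": c.length,
                    **{f"vote_{k}": v for k, v in c.votes.items()},
                    "is_candidate": c.is_candidate,
                }
            )
        pd.DataFrame(lnc_rows).to_csv(out / "lncrna.tsv", sep="\t", index=False)
        for name in ("orfs.tsv", "ssrs.tsv", "lncrna.tsv"):
            record("features", out / name)
        manifest["stages"].append("features")

    # --- alternative splicing ---------------------------------------------
    if config.run_as:
        log.info("AS calling on %d transcripts", len(nr))
        hsps = as_caller.all_vs_all_hsps(
            nr, config.min_hsp_len, config.min_hsp_identity
        )
        events = as_caller.call_as_events(
            hsps,
            nr,
            config.min_hsp_len,
            config.max_overlap,
            config.min_gap,
            config.min_end_distance,
        )
        pd.DataFrame(
            as_caller.events_to_rows(events),
            columns=[
                "continuous_id", "gapped_id", "gap_start", "gap_end",
                "gap_length", "overlap_on_continuous", "orientation", "hsp1", "hsp2",
            ],
        ).to_csv(out / "events.tsv", sep="\t", index=False)
        record("as", out / "events.tsv")
        manifest["stages"].append("as")

    # --- quantification / DE ----------------------------------------------
    if config.run_quant and counts is not None:
        log.info("quantification and DE")
        lengths = pd.Series({t.id: len(t.seq) for t in transcripts})
        common = counts.index.intersection(lengths.index)
        counts_q = counts.loc[common]
        fpkm = quant_de.compute_fpkm(counts_q, lengths.loc[common])
        fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        record("quant", out / "fpkm.tsv")
        tissues = sorted({quant_de.tissue_of(c) for c in counts_q.columns})
        for ta, tb in itertools.combinations(tissues, 2):
            res = quant_de.call_degs(
                counts_q, (ta, tb), config.fc_threshold, config.fdr_threshold
            )
            name = f"degs_{ta}_vs_{tb}.tsv"
            res.to_csv(out / name, sep="\t")
            record("quant", out / name)
        spec = quant_de.select_specific_genes(
            fpkm,
            config.specific_top_n,
            config.specific_min_fpkm,
            config.specific_min_reps,
        )
        spec.to_csv(out / "specific_genes.tsv", sep="\t", index=False)
        record("quant", out / "specific_genes.tsv")
        manifest["stages"].append("quant")
    else:
        fpkm = None

    # --- co-expression network ---------------------------------------------
    if config.run_network and fpkm is not None and traits is not None:
        log.info("co-expression network")
        tf_table = (
            pd.read_csv(config.tf_table_tsv, sep="\t")
            if config.tf_table_tsv
            else None
        )
        ncfg = coexpression.NetworkConfig(
            min_fpkm=config.network_min_fpkm,
            min_kme=config.network_min_kme,
            min_module_size=config.network_min_module_size,
            tree_cut_height=config.network_tree_cut_height,
        )
        # network runs on log2(FPKM+1); the FPKM>=1 prefilter still applies
        # on the raw scale
        expr_net = np.log2(fpkm + 1.0)
        expr_net = expr_net.loc[
            coexpression.prefilter_genes(fpkm, tf_table, ncfg.min_fpkm).index
        ]
        net_cfg = dataclasses.replace(ncfg, min_fpkm=-np.inf)
        result = coexpression.run_wgcna(expr_net, traits, net_cfg, tf_table)
        mod_df = result.modules.to_frame("module")
        mod_df["own_kme"] = [
            result.kme.at[g, m] if m in result.kme.columns else float("nan")
            for g, m in result.modules.items()
        ]
        mod_df.to_csv(out / "modules.tsv", sep="\t")
        result.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        result.module_trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        hub_rows = [
            {"module": m, "gene": g} for m, gs in result.hub_genes.items() for g in gs
        ]
        pd.DataFrame(hub_rows, columns=["module", "gene"]).to_csv(
            out / "hubs.tsv", sep="\t", index=False
        )
        all_hubs = [g for gs in result.hub_genes.values() for g in gs]
        adjacency, _ = coexpression.build_network(expr_net, result.power)
        coexpression.hub_edge_list(adjacency, all_hubs).to_csv(
            out / "hub_edges.tsv", sep="\t", index=False
        )
        for name in ("modules.tsv", "eigengenes.tsv", "module_trait.tsv", "hubs.tsv", "hub_edges.tsv"):
            record("network", out / name)
        manifest["stages"].append("network")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 2) if den else 0.0


def summarize(out_dir) -> dict:
    """Summary statistics recomputed purely from the stage output files.

    Counts use the reporting vocabulary of full-length transcriptome studies
    (non-redundant transcripts, ORFs, complete CDSs, SSRs, compound SSRs, AS
    events, lncRNA candidates, DEGs per tissue pair, modules, hub genes) plus
    derived percentages computed from those counts.
    """
    out = Path(out_dir)
    s: dict = {}

    def read(name: str) -> Optional[pd.DataFrame]:
        p = out / name
        if not p.exists():
            return None
        try:
            return pd.read_csv(p, sep="\t")
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    n_input = 0
    fa_in = out / "input_transcripts.fa"
    if fa_in.exists():
        n_input = sum(1 for line in fa_in.open() if line.startswith(">"))
    nr_fa = out / "nr.fa"
    n_nr = (
        sum(1 for line in nr_fa.open() if line.startswith(">")) if nr_fa.exists() else 0
    )
    s["input_transcripts"] = n_input
    s["non_redundant_transcripts"] = n_nr
    if n_input:
        s["pct_non_redundant"] = _pct(n_nr, n_input)

    orfs = read("orfs.tsv")
    if orfs is not None:
        s["orfs"] = len(orfs)
        s["complete_cds"] = int((orfs["completeness"] == "complete").sum()) if len(orfs) else 0
        s["pct_complete_cds"] = _pct(s["complete_cds"], s["orfs"])

    ssrs = read("ssrs.tsv")
    if ssrs is not None:
        s["ssrs"] = len(ssrs)
        if len(ssrs):
            per_seq = ssrs.groupby("ID").size()
            s["ssr_containing_sequences"] = int(len(per_seq))
            s["sequences_with_multiple_ssrs"] = int((per_seq > 1).sum())
            s["compound_ssrs"] = int(ssrs["compound_group"].notna().sum())
        else:
            s["ssr_containing_sequences"] = 0
            s["sequences_with_multiple_ssrs"] = 0
            s["compound_ssrs"] = 0
        s["pct_compound_ssrs"] = _pct(s["compound_ssrs"], s["ssrs"])
        s["pct_ssr_containing"] = _pct(s["ssr_containing_sequences"], n_nr)

    events = read("events.tsv")
    if events is not None:
        s["as_events"] = len(events)

    lnc = read("lncrna.tsv")
    if lnc is not None:
        s["lncrna_candidates"] = int(lnc["is_candidate"].sum()) if len(lnc) else 0
        s["pct_lncrna"] = _pct(s["lncrna_candidates"], n_nr)

    for p in sorted(out.glob("degs_*_vs_*.tsv")):
        df = pd.read_csv(p, sep="\t", index_col=0)
        pair = p.stem.replace("degs_", "")
        s[f"degs_{pair}"] = int(df["is_deg"].sum()) if len(df) else 0

    mods = read("modules.tsv")
    if mods is not None:
        s["modules"] = (
            int(mods.loc[mods["module"] != "grey", "module"].nunique()) if len(mods) else 0
        )
    hubs = read("hubs.tsv")
    if hubs is not None:
        s["hub_genes"] = len(hubs)
    return s
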