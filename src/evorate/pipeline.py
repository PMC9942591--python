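"""End-to-end pipeline orchestration.

A run goes: obtain the query-anchored MSA (directly, or by selecting
representatives from a homolog hit table) -> obtain the tree (user-supplied
Newick or corrected-distance neighbor joining) -> fit the gamma shape ->
per-site posterior rates -> nine-grade conservation scores over query
positions -> optionally map grades onto a structure and emit viewer
scripts. Every stage logs its parameters and counts to run.log, and all
outputs are deterministic for a fixed config.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy

from . import grading, homologs, phylogeny, rates, seq_io, structure
from .errors import (
    ExternalToolNotFoundError,
    ParseError,
    TooFewHomologuesError,
)

logger = logging.getLogger("evorate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run. Exactly one input mode is active:
    either ``msa_path`` or (``query_fasta`` + ``hits_path`` + ``sequences_path``)."""

    out_dir: Path
    query_id: str
    # MSA mode
    msa_path: Path | None = None
    msa_format: Literal["fasta", "clustal"] = "fasta"
    # hit-table mode
    query_fasta: Path | None = None
    hits_path: Path | None = None
    hits_format: Literal["tsv", "blast6"] = "tsv"
    sequences_path: Path | None = None
    aligner: str | None = None  # external MSA executable (e.g. "mafft")
    # optional extras
    tree_path: Path | None = None
    structure_path: Path | None = None
    chain: str | None = None
    structure_format: Literal["auto", "pdb", "mmcif"] = "auto"
    # parameters
    alphabet: Literal["protein", "nucleotide"] | None = None
    selection: homologs.SelectionConfig = field(default_factory=homologs.SelectionConfig)
    n_categories: int = rates.DEFAULT_K
    ci_level: float = rates.DEFAULT_CI
    color_scale: Literal["standard", "color_blind"] = "standard"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        msa_mode = self.msa_path is not None
        hits_mode = self.hits_path is not None
        if msa_mode == hits_mode:
            raise ValueError(
                "exactly one input mode: --msa, or --query-fasta with --hits "
                "and --sequences"
            )
        if hits_mode and (self.query_fasta is None or self.sequences_path is None):
            raise ValueError("hit-table mode needs --query-fasta and --sequences")


@dataclass
class RunResult:
    config: RunConfig
    alignment: seq_io.Alignment
    tree: dendropy.Tree
    alpha: float
    gamma: rates.GammaDiscretization
    site_results: list[rates.SiteRateResult]
    grades: list[grading.GradeResult]
    chain_grade_maps: list[structure.ChainGradeMap]
    outputs: dict[str, Path]


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def ingest_external_msa_tool(
    sequences: Sequence[tuple[str, str]], aligner: str, workdir: Path, query_id: str
) -> seq_io.Alignment:
    """Align representative sequences with an external MSA tool.

    Entirely optional: pre-aligned (MSA-mode) runs never reach this. The
    tool is invoked on a temporary FASTA and its FASTA output parsed back.
    """
    exe = shutil.which(aligner)
    if exe is None:
        raise ExternalToolNotFoundError(
            f"aligner {aligner!r} not found on PATH; supply a pre-built MSA "
            "with --msa instead"
        )
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        in_fa = Path(tmp) / "reps.fasta"
        out_fa = Path(tmp) / "aligned.fasta"
        seq_io.write_fasta(list(sequences), in_fa)
        name = Path(aligner).name.lower()
        if "mafft" in name:
            cmd = [exe, "--auto", "--anysymbol", str(in_fa)]
        elif "muscle" in name:
            cmd = [exe, "-align", str(in_fa), "-output", str(out_fa)]
        elif "clustal" in name:
            cmd = [exe, f"-INFILE={in_fa}", "-OUTPUT=FASTA", f"-OUTFILE={out_fa}"]
        else:  # prank and friends: tool reads FASTA on stdin-style args
            cmd = [exe, str(in_fa)]
        logger.info("external aligner: %s", " ".join(cmd))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ParseError(f"aligner failed: {proc.stderr[-2000:]}")
        if not out_fa.exists():
            out_fa.write_text(proc.stdout)
        return seq_io.read_alignment(out_fa, "fasta", query_id)


def _alignment_from_hits(config: RunConfig) -> seq_io.Alignment:
    query_seqs = seq_io.read_fasta_sequences(config.query_fasta)
    if config.query_id not in query_seqs:
        from .errors import QueryMissingError

        raise QueryMissingError(
            f"query {config.query_id!r} not found in {config.query_fasta}"
        )
    query_seq = query_seqs[config.query_id].replace("-", "")
    sequences = seq_io.read_fasta_sequences(config.sequences_path)
    if config.hits_format == "blast6":
        hits = homologs.read_hits_blast_tabular(
            config.hits_path, sequences, query_length=len(query_seq)
        )
    else:
        hits = homologs.read_hits_tsv(config.hits_path, sequences)
    query_hit = homologs.Hit(
        subject_id=config.query_id,
        e_value=0.0,
        identity_to_query=1.0,
        coverage_of_query=1.0,
        sequence=query_seq,
    )
    selected = homologs.select_homologues(hits, query_hit, config.selection)
    logger.info(
        "selection: %d hits -> %d representatives (target %d)",
        len(hits),
        len(selected),
        config.selection.n_representatives,
    )
    pairs = [(h.subject_id, h.sequence) for h in selected]
    if config.aligner:
        return ingest_external_msa_tool(
            pairs, config.aligner, config.out_dir, config.query_id
        )
    lengths = {len(s) for _, s in pairs}
    if len(lengths) == 1:
        records = [seq_io.SequenceRecord(n, s) for n, s in pairs]
        alphabet = config.alphabet or seq_io.detect_alphabet(records)
        return seq_io.Alignment(
            records=records, query_id=config.query_id, alphabet=alphabet
        )
    raise ParseError(
        "selected representatives are unaligned and no --aligner was "
        "configured; align them externally and rerun with --msa"
    )


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; see the module docstring for the stages."""
    handler = _setup_logging(config.out_dir, config.log_level)
    try:
        return _run_stages(config)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig) -> RunResult:
    out = config.out_dir
    outputs: dict[str, Path] = {"log": out / "run.log"}

    # --- stage 1: alignment
    if config.msa_path is not None:
        alignment = seq_io.read_alignment(
            config.msa_path, config.msa_format, config.query_id, config.alphabet
        )
    else:
        alignment = _alignment_from_hits(config)
    logger.info(
        "alignment: %d sequences x %d columns, alphabet=%s, query=%s",
        alignment.n_sequences,
        alignment.n_sites,
        alignment.alphabet,
        config.query_id,
    )
    # count policy applies to whatever set reaches the rate computation
    homologs.enforce_counts(list(alignment.records), config.selection)
    outputs["msa"] = out / "msa.fasta"
    seq_io.write_alignment(alignment, outputs["msa"])

    # --- stage 2: tree
    if config.tree_path is not None:
        tree = phylogeny.read_newick(config.tree_path)
        phylogeny.validate_tree_against_alignment(tree, alignment)
        logger.info("tree: read %d-leaf tree from %s", alignment.n_sequences, config.tree_path)
    else:
        D = phylogeny.pairwise_distances(alignment)
        tree = phylogeny.build_nj(D)
        logger.info("tree: neighbor joining over corrected distances")
    outputs["tree"] = out / "tree.nwk"
    phylogeny.write_newick(tree, outputs["tree"])

    # --- stage 3: rates
    model = rates.build_model(alignment.alphabet)
    alpha = rates.estimate_alpha(alignment, tree, model, K=config.n_categories)
    gamma = rates.discretize_gamma(alpha, config.n_categories)
    logger.info("rates: alpha=%.4f, K=%d", alpha, config.n_categories)
    site_results = rates.posterior_rates(
        alignment, tree, model, gamma, ci_level=config.ci_level
    )
    outputs["rates"] = out / "rates.tsv"
    rates.write_rates_tsv(site_results, alignment, outputs["rates"])

    # --- stage 4: grading
    qmap = seq_io.build_query_map(alignment)
    grade_results = grading.grade_query_positions(site_results, alignment, qmap)
    n_unreliable = sum(1 for g in grade_results if not g.reliable)
    logger.info(
        "grading: %d query positions, %d flagged unreliable",
        len(grade_results),
        n_unreliable,
    )
    outputs["grades_tsv"] = out / "grades.tsv"
    outputs["grades_json"] = out / "grades.json"
    grading.write_grades_tsv(grade_results, outputs["grades_tsv"])
    grading.write_grades_json(grade_results, outputs["grades_json"])

    # --- stage 5: structure mapping (optional)
    chain_maps: list[structure.ChainGradeMap] = []
    if config.structure_path is not None:
        smodel = structure.parse_structure(config.structure_path, config.structure_format)
        chain_id = config.chain or smodel.chain_ids[0]
        query_seq = alignment.query.ungapped()
        grades_by_pos = {g.query_position: g.grade for g in grade_results}
        primary = structure.build_chain_grade_map(
            smodel, chain_id, query_seq, grades_by_pos, alignment.alphabet
        )
        chain_maps = structure.propagate_identical_chains(smodel, primary)
        logger.info(
            "structure: chain %s identity %.3f; grades propagated to %d chain(s)",
            chain_id,
            primary.identity_to_query,
            len(chain_maps),
        )
        ext = "pdb" if smodel.source_format == "pdb" else "cif"
        outputs["graded_structure"] = out / f"graded.{ext}"
        structure.write_graded_structure(
            smodel, chain_maps, outputs["graded_structure"], smodel.source_format
        )
        scripts = structure.emit_coloring_scripts(
            chain_maps, out, outputs["graded_structure"].name, config.color_scale
        )
        outputs["pymol_script"] = scripts["pymol"]
        outputs["chimerax_script"] = scripts["chimerax"]

    return RunResult(
        config=config,
        alignment=alignment,
        tree=tree,
        alpha=alpha,
        gamma=gamma,
        site_results=site_results,
        grades=grade_results,
        chain_grade_maps=chain_maps,
        outputs=outputs,
    )


def run_subtree(
    previous: RunResult, clade_leaves: Iterable[str], out_dir: Path | None = None
) -> RunResult:
    """Re-run the downstream stages on a user-selected clade.

    The induced subtree (branch lengths preserved) is used as the fixed
    tree; the alignment is restricted to the clade's leaves with all-gap
    columns dropped; the gamma shape is re-fitted on the restricted data.
    Useful to detect regions conserved only within a subfamily.
    """
    cfg = previous.config
    out = Path(out_dir) if out_dir is not None else cfg.out_dir / "subtree"
    subtree, sub_alignment = phylogeny.extract_subtree(
        previous.tree,
        clade_leaves,
        previous.alignment,
        min_homologues=cfg.selection.min_homologues,
    )
    out.mkdir(parents=True, exist_ok=True)
    sub_msa = out / "input_msa.fasta"
    sub_tree = out / "input_tree.nwk"
    seq_io.write_alignment(sub_alignment, sub_msa)
    phylogeny.write_newick(subtree, sub_tree)
    new_cfg = replace(
        cfg,
        out_dir=out,
        msa_path=sub_msa,
        msa_format="fasta",
        query_fasta=None,
        hits_path=None,
        sequences_path=None,
        tree_path=sub_tree,
        alphabet=sub_alignment.alphabet,
    )
    return run(new_cfg)
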