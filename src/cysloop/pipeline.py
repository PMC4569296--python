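"""End-to-end orchestration: simulate -> groom -> walk -> orf -> quantify ->
annotate -> identity, with a checksummed manifest for reproducibility.

The run configuration is a flat YAML/dict: a root seed drives every stage's
randomness, and re-running the same configuration reproduces all outputs
byte-identically.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import annotate_all, reports_to_frame
from .grooming import groom_reads
from .identity import identity_matrix
from .io import read_msa, sha256_of, write_fasta
from .orf import find_morf, transcript_report
from .params import PipelineParams
from .quantify import abundance_table, count_genes, relative_abundance
from .synthetic import (MotifPlan, SyntheticTruth, TranscriptomeSpec,
                        make_synthetic_transcriptome, simulate_reads,
                        write_truth)
from .walker import find_seeds, walk


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    n_genes: int = 3
    n_pairs: int = 4000
    read_length: int = 100
    library: str = "brain"
    error_rate: float = 0.002
    quality_tail_prob: float = 0.01
    bait_fasta: str | None = None    # default: first truth protein fragment
    msa_fasta: str | None = None     # for the identity stage
    params: PipelineParams = field(default_factory=PipelineParams)
    motif_plan: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d:
            d["params"] = PipelineParams.from_dict(d["params"])
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in d.items() if k in known})


def _default_plans(config: RunConfig) -> dict[str, MotifPlan]:
    if config.motif_plan:
        return {g: MotifPlan(**p) for g, p in config.motif_plan.items()}
    plans = {"g00": MotifPlan(vicinal_cc=False)}  # rdl-like anion subunit
    if config.n_genes > 1:
        plans["g01"] = MotifPlan(
            vicinal_cc=True,
            tm2_prime_residues={-2: "S", -1: "E", 0: "Q", 13: "V", 20: "E"})
    return plans


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute every stage under one run directory; returns the manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": config.params.to_dict(),
        "stages": [],
        "outputs": {},
    }

    def _done(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = sha256_of(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))

    try:
        # -- simulate
        spec = TranscriptomeSpec(
            n_genes=config.n_genes, motif_plan=_default_plans(config),
            rng_seed=config.seed, error_rate=config.error_rate,
            libraries=(config.library,))
        spec.quality_model = type(spec.quality_model)(
            tail_prob=config.quality_tail_prob)
        truth = make_synthetic_transcriptome(spec)
        reads = simulate_reads(truth, config.library, config.n_pairs,
                               config.read_length, rng_seed=config.seed + 1)
        paths = write_truth(truth, out / "truth",
                            {config.library: reads})
        _done("simulate", *paths.values())

        # -- groom
        db = groom_reads(reads, config.params)
        db.save(out / "db")
        _done("groom", out / "db" / "groomed.fasta", out / "db" / "stats.tsv")

        # -- seeds + walk (one walk per motif gene, seeded by its bait)
        contigs: list[tuple[str, str]] = []
        walk_rows = []
        for gene, plan in truth.plans.items():
            if plan is None:
                continue
            protein = truth.transcript(gene).protein
            bait = protein[40:140]
            hits = find_seeds(bait, db, config.params)
            if not hits:
                walk_rows.append({"gene": gene, "status": "no_seed"})
                continue
            result = walk(hits[0].seed_seq, db, config.params)
            contigs.append((f"contig_{gene}", result.contig))
            walk_rows.append({
                "gene": gene, "status": result.status3,
                "contig_length": len(result.contig),
                "n_steps": len(result.state3.trace) + len(result.state5.trace),
                "seed_read": hits[0].read_id, "seed_score": hits[0].score,
            })
        contig_path = out / "contigs.fasta"
        write_fasta(contigs, contig_path)
        import pandas as pd
        trace_path = out / "walk.tsv"
        pd.DataFrame(walk_rows).to_csv(trace_path, sep="\t", index=False)
        _done("walk", contig_path, trace_path)

        # -- orf
        models = [find_morf(seq, id=name,
                            min_codons=config.params.min_orf_codons)
                  for name, seq in contigs]
        orf_path = out / "orf.tsv"
        transcript_report(models).to_csv(orf_path, sep="\t", index=False)
        _done("orf", orf_path)

        # -- quantify (all truth genes, relative to actin)
        morfs = {t.id: t.morf_seq for t in truth.transcripts}
        counts = count_genes(db, morfs, config.params)
        records = relative_abundance(
            counts, {g: len(m) for g, m in morfs.items()},
            actin_id=truth.actin_id, library=config.library,
            reads_tested=len(db))
        ab_path = out / "abundance.tsv"
        abundance_table(records).to_csv(ab_path, sep="\t", index=False)
        _done("quantify", ab_path)

        # -- annotate assembled proteins
        proteins = [(m.id, m.protein) for m in models]
        reports = annotate_all(proteins)
        rep_path = out / "reports.json"
        rep_path.write_text(json.dumps([r.to_dict() for r in reports],
                                       indent=1, sort_keys=True))
        reports_to_frame(reports).to_csv(out / "reports.tsv", sep="\t",
                                         index=False)
        _done("annotate", rep_path, out / "reports.tsv")

        # -- identity (consumes an MSA; aligns with mafft when available)
        msa = None
        if config.msa_fasta:
            msa = read_msa(config.msa_fasta)
        elif len(proteins) >= 2 and shutil.which("mafft"):
            msa = align_with_mafft(proteins)
        if msa:
            mat = identity_matrix(msa, nj_order=len(msa) > 2)
            id_path = out / "identity.tsv"
            mat.write_tsv(id_path)
            _done("identity", id_path)
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        raise
    return manifest


def align_with_mafft(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Align protein records with the external mafft binary."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(records, inp)
        res = subprocess.run(["mafft", "--quiet", "--auto", str(inp)],
                             capture_output=True, text=True, check=True)
        outp = Path(tmp) / "out.fasta"
        outp.write_text(res.stdout)
        return read_msa(outp)


def validate_proteins(records: list[tuple[str, str]],
                      msa: list[tuple[str, str]] | None = None):
    """Worked-example report for user-supplied (e.g. downloaded accession)
    protein sequences: residue count, MW, Cys-loop span, and, when an MSA
    is given, the pairwise identity matrix.
    """
    import pandas as pd

    from .annotate import annotate
    from .orf import molecular_weight

    rows = []
    for name, seq in records:
        rep = annotate(seq, id=name)
        rows.append({
            "id": name,
            "n_aa": len(seq),
            "mw_kda": round(molecular_weight(seq), 1),
            "mw_kda_rounded": round(molecular_weight(seq)),
            "cys_loop_gap": rep.cys_loop_gap,
            "class_call": rep.class_call,
        })
    table = pd.DataFrame(rows)
    mat = identity_matrix(msa) if msa else None
    return table, mat
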