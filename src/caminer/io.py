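"""Readers and writers for the standard text formats the pipeline consumes.

Formats: FASTA (Biopython), HMMER3 domain tables (``--domtblout``), 12-column
tabular BLAST (``-outfmt 6``), Phobius short format, TSV sample metadata, and
two-column CSV time series. The synthetic-data generators write fixtures with
the same writers these readers are tested against (round-trip tests).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidate_screen import (
    CandidateReport,
    DomainHit,
    ProteinRecord,
    SampleMetadata,
    SimilarityHit,
)
from .reactor import PressureSeries
from .stopped_flow import Trace

__all__ = [
    "read_protein_fasta",
    "write_protein_fasta",
    "write_gene_fasta",
    "read_domtbl",
    "write_domtbl",
    "read_blast_tab",
    "write_blast_tab",
    "read_phobius_short",
    "write_phobius_short",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_trace_csv",
    "write_trace_csv",
    "read_pressure_csv",
    "write_pressure_csv",
    "write_candidate_reports",
]


# ---------------------------------------------------------------------------
# FASTA


def write_protein_fasta(path, proteins: Sequence[ProteinRecord]) -> None:
    """Protein FASTA; sample linkage and partial flags ride in the description."""
    records = []
    for p in proteins:
        desc = f"sample={p.sample_id} partial={int(p.start_truncated)}{int(p.end_truncated)}"
        records.append(SeqRecord(Seq(p.sequence), id=p.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def write_gene_fasta(path, proteins: Sequence[ProteinRecord]) -> None:
    records = [
        SeqRecord(Seq(p.gene_nt), id=p.id, description="")
        for p in proteins
        if p.gene_nt is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_desc(description: str) -> Tuple[str, bool, bool]:
    sample, flags = "", "00"
    for field in description.split():
        if field.startswith("sample="):
            sample = field[len("sample="):]
        elif field.startswith("partial="):
            flags = field[len("partial="):]
    return sample, flags[0] == "1", flags[1] == "1"


def read_protein_fasta(path, genes_path=None) -> List[ProteinRecord]:
    """Read proteins (and optionally their genes) back into records."""
    genes: Dict[str, str] = {}
    if genes_path is not None and Path(genes_path).exists():
        genes = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(genes_path), "fasta")}
    out = []
    for r in SeqIO.parse(str(path), "fasta"):
        sample, st, et = _parse_desc(r.description)
        out.append(
            ProteinRecord(
                id=r.id,
                sequence=str(r.seq).upper(),
                gene_nt=genes.get(r.id),
                sample_id=sample,
                start_truncated=st,
                end_truncated=et,
            )
        )
    return out


# ---------------------------------------------------------------------------
# HMMER3 domain table (hmmscan --domtblout): whitespace-delimited, 22 fixed
# columns plus a free-text description of target.

_DOMTBL_HEADER = """\
#                                                                            --- full sequence --- -------------- this domain -------------         hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
"""


def write_domtbl(path, hits: Sequence[DomainHit], protein_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write hits as an hmmscan domain table (target = profile, query = protein)."""
    lengths = protein_lengths or {}
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for h in hits:
            qlen = lengths.get(h.protein_id, h.env_to)
            row = (
                f"{h.profile_name:<20} {h.profile_accession:<10} {h.env_to - h.env_from + 1:5d} "
                f"{h.protein_id:<20} {'-':<10} {qlen:5d} "
                f"{h.i_evalue:9.2g} {h.bit_score:6.1f} {0.0:5.1f} "
                f"{1:3d} {1:3d} {h.i_evalue:9.2g} {h.i_evalue:9.2g} {h.bit_score:6.1f} {0.0:5.1f} "
                f"{1:5d} {h.env_to - h.env_from + 1:5d} {h.env_from:5d} {h.env_to:5d} "
                f"{h.env_from:5d} {h.env_to:5d} {0.95:4.2f} -\n"
            )
            fh.write(row)


def read_domtbl(path) -> List[DomainHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split(None, 22)
            if len(f) < 22:
                raise ValueError(f"malformed domain-table row: {line!r}")
            hits.append(
                DomainHit(
                    protein_id=f[3],
                    profile_accession=f[1],
                    profile_name=f[0],
                    i_evalue=float(f[12]),
                    bit_score=float(f[13]),
                    env_from=int(f[19]),
                    env_to=int(f[20]),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Tabular BLAST (-outfmt 6, 12 columns)

_BLAST_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_blast_tab(path, hits: Sequence[SimilarityHit],
                    query_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write hits as 12-column tabular BLAST.

    The narrow format carries no subject title, so titles are not preserved
    on round trip; alignment coordinates are reconstructed from the query
    coverage when query lengths are known.
    """
    lengths = query_lengths or {}
    rows = []
    for h in hits:
        qlen = lengths.get(h.query_id)
        cov = h.query_coverage if h.query_coverage == h.query_coverage else 100.0
        alen = max(1, int(round(cov / 100.0 * qlen))) if qlen else 100
        mism = int(round(alen * (1 - h.pct_identity / 100.0)))
        rows.append(
            (h.query_id, h.subject_id, f"{h.pct_identity:.3f}", alen, mism, 0,
             1, alen, 1, alen, f"{h.evalue:.2e}", f"{200.0:.1f}")
        )
    pd.DataFrame(rows, columns=_BLAST_COLS).to_csv(path, sep="\t", header=False, index=False)


def read_blast_tab(path, query_lengths: Optional[Mapping[str, int]] = None) -> List[SimilarityHit]:
    df = pd.read_csv(path, sep="\t", names=_BLAST_COLS, header=None, comment="#")
    lengths = query_lengths or {}
    hits = []
    for row in df.itertuples(index=False):
        qlen = lengths.get(row.qseqid)
        cov = 100.0 * (row.qend - row.qstart + 1) / qlen if qlen else float("nan")
        hits.append(
            SimilarityHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                evalue=float(row.evalue),
                pct_identity=float(row.pident),
                subject_title=str(row.sseqid),
                query_coverage=cov,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Phobius short format


def write_phobius_short(path, topology: Mapping[str, Tuple[bool, bool]]) -> None:
    """Phobius short output: SEQENCE ID, TM count, SP flag, prediction string."""
    with open(path, "w") as fh:
        fh.write("SEQENCE ID                     TM SP PREDICTION\n")
        for pid in sorted(topology):
            sp, tm = topology[pid]
            tm_count = 1 if tm else 0
            sp_flag = "Y" if sp else "0"
            if sp and tm:
                pred = "n8-20c25/26o62-81i"
            elif sp:
                pred = "n8-20c25/26o"
            elif tm:
                pred = "i12-34o"
            else:
                pred = "o"
            fh.write(f"{pid:<30} {tm_count:2d} {sp_flag}  {pred}\n")


def read_phobius_short(path) -> Dict[str, Tuple[bool, bool]]:
    out: Dict[str, Tuple[bool, bool]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.upper().startswith("SEQENCE"):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"malformed Phobius row: {line!r}")
            out[f[0]] = (f[2] == "Y", int(f[1]) > 0)
    return out


# ---------------------------------------------------------------------------
# Metadata and time-series tables


def write_metadata_tsv(path, metadata: Sequence[SampleMetadata]) -> None:
    pd.DataFrame(
        [(m.sample_id, m.temperature, m.pH, m.description) for m in metadata],
        columns=["sample_id", "temperature_c", "ph", "description"],
    ).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> List[SampleMetadata]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMetadata(
            sample_id=str(r.sample_id),
            temperature=float(r.temperature_c),
            pH=float(r.ph),
            description="" if pd.isna(r.description) else str(r.description),
        )
        for r in df.itertuples(index=False)
    ]


def write_trace_csv(path, trace: Trace) -> None:
    pd.DataFrame({"time_s": trace.time, "absorbance": trace.absorbance}).to_csv(
        path, index=False
    )


def read_trace_csv(path) -> Trace:
    df = pd.read_csv(path)
    return Trace(
        time=df["time_s"].to_numpy(dtype=float),
        absorbance=df["absorbance"].to_numpy(dtype=float),
    )


def write_pressure_csv(path, series: PressureSeries) -> None:
    """Pressure series CSV in field units (minutes, bar)."""
    pd.DataFrame(
        {"time_min": series.time, "pressure_bar": series.pressure / 1e5}
    ).to_csv(path, index=False)


def read_pressure_csv(path) -> PressureSeries:
    df = pd.read_csv(path)
    return PressureSeries(
        time=df["time_min"].to_numpy(dtype=float),
        pressure=df["pressure_bar"].to_numpy(dtype=float) * 1e5,
    )


# ---------------------------------------------------------------------------
# Candidate report output


def write_candidate_reports(outdir, reports: Sequence[CandidateReport]) -> None:
    """TSV table of per-protein outcomes plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in reports:
        rows.append(
            {
                "protein_id": r.protein_id,
                "branch": r.branch or "none",
                "motif_hits": ";".join(
                    f"{m}:{','.join(map(str, pos))}" for m, pos in r.motif_hits.items()
                ),
                "has_start": r.boundary_ok[0],
                "has_stop": r.boundary_ok[1],
                "length_ok": r.length_ok,
                "sp_or_tm": r.sp_or_tm,
                "env_ok": r.env_ok,
                "cluster_representative": r.cluster_representative,
                "selected": r.selected,
                "reasons": " | ".join(r.reasons),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    summary = {
        "n_proteins": len(reports),
        "n_selected": sum(r.selected for r in reports),
        "selected_ids": sorted(r.protein_id for r in reports if r.selected),
        "branches": {
            "scap": sum(r.branch == "scap" for r in reports),
            "fnr": sum(r.branch == "fnr" for r in reports),
            "none": sum(r.branch is None for r in reports),
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
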