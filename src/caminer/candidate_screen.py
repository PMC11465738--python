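"""Two-branch candidate selection cascade for carbonic-anhydrase mining.

Predicted proteins from extreme-environment metagenomes are screened along
two evidence branches: proteins with at least one hit against a curated set
of CA-related Pfam profiles (the "SCAP" branch), and the remainder screened
by similarity against a keyword-filtered reference database (the "fnr"
branch, e-value <= 1e-50). Surviving proteins are then curated: beta-CA
active-site motifs (CxDxR, HxxC), gene start/stop codons, protein length
against the family mean, signal-peptide/transmembrane flags, sampling-site
environment (temperature and alkalinity), and greedy de-duplication at 90%
pairwise identity.

All coordinates are 1-based inclusive. All boundary comparisons are
inclusive: e-value <= cutoff is kept, identity >= cutoff is merged,
temperature >= threshold is kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "SampleMetadata",
    "DomainHit",
    "SimilarityHit",
    "ScreenConfig",
    "CandidateReport",
    "ReferentialIntegrityError",
    "filter_reference_by_keywords",
    "select_scap_hits",
    "select_similarity_hits",
    "scan_motifs",
    "check_gene_boundaries",
    "pairwise_identity",
    "dedup_candidates",
    "filter_samples_by_environment",
    "compile_report",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Curated set of CA-related Pfam profiles (versioned accessions) used as
#: the domain-evidence branch of the screen.
SCAP_ACCESSIONS = frozenset(
    {
        "PF00194.23",  # Carb_anhydrase (alpha)
        "PF00484.21",  # Pro_CA (beta)
        "PF00101.22",  # RuBisCO_small
        "PF08936.12",  # CsoSCA
        "PF00016.22",  # RuBisCO_large
        "PF02788.18",  # RuBisCO_large_N
        "PF00936.21",  # BMC
        "PF03319.15",  # EutN_Ccml
    }
)

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TGA", "TAG"})


class ReferentialIntegrityError(ValueError):
    """An annotation row references a protein id absent from the input set."""


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein, optionally paired with its source gene.

    ``partial_flags`` marks contig-edge gene predictions whose start or end
    is truncated; such genes are exempt from the length-divisible-by-3
    invariant but will fail the boundary checks downstream.
    """

    id: str
    sequence: str
    gene_nt: Optional[str] = None
    sample_id: str = ""
    start_truncated: bool = False
    end_truncated: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"protein {self.id!r}: sequence must be uppercase")
        bad = set(self.sequence) - _PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id!r}: non-residue characters {sorted(bad)}")
        if self.gene_nt is not None and len(self.gene_nt) % 3 != 0:
            if not (self.start_truncated or self.end_truncated):
                raise ValueError(
                    f"protein {self.id!r}: gene length {len(self.gene_nt)} not a "
                    "multiple of 3 and no partial flag set"
                )


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    temperature: float  # degrees C at the sampling site
    pH: float
    description: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.pH <= 14.0):
            raise ValueError(f"sample {self.sample_id!r}: pH {self.pH} outside [0, 14]")
        if not (self.temperature == self.temperature and abs(self.temperature) != float("inf")):
            raise ValueError(f"sample {self.sample_id!r}: non-finite temperature")


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit (one row of an hmmscan domain table)."""

    protein_id: str
    profile_accession: str  # versioned Pfam accession, e.g. PF00484.21
    profile_name: str
    i_evalue: float
    bit_score: float
    env_from: int  # 1-based inclusive envelope coordinates on the protein
    env_to: int

    def __post_init__(self) -> None:
        if self.env_from > self.env_to:
            raise ValueError(f"domain hit on {self.protein_id!r}: env_from > env_to")
        if self.i_evalue < 0:
            raise ValueError(f"domain hit on {self.protein_id!r}: negative i-evalue")


@dataclass(frozen=True)
class SimilarityHit:
    """One protein-vs-reference similarity hit (tabular BLAST row)."""

    query_id: str
    subject_id: str
    evalue: float
    pct_identity: float
    subject_title: str = ""
    query_coverage: float = float("nan")

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"similarity hit {self.query_id!r}: negative e-value")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"similarity hit {self.query_id!r}: identity outside [0, 100]")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and reference sets of the selection cascade.

    Defaults reproduce the published screen: the eight-profile SCAP set, the
    1e-50 similarity cutoff, 90% identity de-duplication, and the final
    shortlist environment rule (sampling temperature >= 90 degrees C, alkaline
    pH). ``family_mean_length`` is the mean length of the CA family used for
    the length plausibility window; it is an input, not a published number.
    """

    scap_accessions: frozenset = SCAP_ACCESSIONS
    fnr_keywords: tuple = ("carbonic anhydrase", "carbonic dehydratase", "ca")
    evalue_cutoff: float = 1e-50
    identity_cutoff: float = 90.0
    min_temperature: float = 90.0
    require_alkaline: bool = True
    motifs: tuple = ("CxDxR", "HxxC")
    start_codons: frozenset = DEFAULT_START_CODONS
    stop_codons: frozenset = DEFAULT_STOP_CODONS
    family_mean_length: int = 180
    length_window: tuple = (0.5, 2.0)
    sp_tm_policy: str = "flag"  # "flag" records SP/TM presence; "reject" excludes

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0 or self.identity_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        lo, hi = self.length_window
        if not lo < hi:
            raise ValueError("length window low bound must be below high bound")
        if self.sp_tm_policy not in ("flag", "reject"):
            raise ValueError("sp_tm_policy must be 'flag' or 'reject'")

    @property
    def length_bounds(self) -> tuple:
        lo, hi = self.length_window
        return lo * self.family_mean_length, hi * self.family_mean_length

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        kwargs = dict(d)
        for key in ("scap_accessions", "start_codons", "stop_codons"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        for key in ("fnr_keywords", "motifs", "length_window"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class CandidateReport:
    """Per-protein outcome of the cascade with per-step reasons."""

    protein_id: str
    branch: Optional[str]  # "scap" | "fnr" | None
    motif_hits: dict  # motif pattern -> list of 1-based positions
    boundary_ok: tuple  # (has_start, has_stop)
    length_ok: bool
    sp_or_tm: bool
    env_ok: bool
    cluster_representative: bool
    selected: bool
    reasons: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Branch construction


def _tokens(text: str) -> list:
    """Maximal alphabetic runs, the tokenization used for keyword matching."""
    return re.findall(r"[A-Za-z]+", text)


def filter_reference_by_keywords(titles: Sequence[str], keywords: Sequence[str]) -> list:
    """Indices of titles matching any keyword.

    Multi-word keywords match as case-insensitive substrings on word
    boundaries; single-word keywords (notably the deliberately short "ca")
    must equal a whole token, so "calcium-binding protein" is not matched
    but "Ca channel subunit" is.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    single = {k.casefold() for k in keywords if len(_tokens(k)) == 1}
    multi = [k for k in keywords if len(_tokens(k)) > 1]
    multi_res = [
        re.compile(r"(?<![A-Za-z])" + r"[^A-Za-z]+".join(map(re.escape, _tokens(k))) + r"(?![A-Za-z])",
                   re.IGNORECASE)
        for k in multi
    ]
    kept = []
    for i, title in enumerate(titles):
        toks = {t.casefold() for t in _tokens(title)}
        if toks & single or any(rx.search(title) for rx in multi_res):
            kept.append(i)
    return kept


def select_scap_hits(hits: Iterable[DomainHit], config: ScreenConfig) -> set:
    """Protein ids with at least one hit against the SCAP profile set.

    No e-value threshold is applied here; the domain table's own reporting
    thresholds are taken as given.
    """
    return {h.protein_id for h in hits if h.profile_accession in config.scap_accessions}


def select_similarity_hits(hits: Iterable[SimilarityHit], config: ScreenConfig) -> set:
    """Query ids with at least one hit at e-value <= cutoff (inclusive)."""
    kept = set()
    for h in hits:
        if h.evalue < 0:
            raise ValueError("negative e-value")
        if h.evalue <= config.evalue_cutoff:
            kept.add(h.query_id)
    return kept


# ---------------------------------------------------------------------------
# Sequence-level curation


def _compile_motif(pattern: str) -> str:
    out = []
    for ch in pattern:
        if ch == "x":
            out.append(f"[{AMINO_ACIDS}]")
        elif ch.upper() in AMINO_ACIDS:
            out.append(ch.upper())
        else:
            raise ValueError(f"motif pattern {pattern!r}: invalid letter {ch!r}")
    return "".join(out)


def scan_motifs(sequence: str, motifs: Sequence[str]) -> dict:
    """All (possibly overlapping) 1-based match positions per motif pattern.

    Lowercase ``x`` in a pattern is a wildcard over the 20 standard residues;
    uppercase letters are literal residues.
    """
    if not sequence:
        raise ValueError("empty sequence")
    result = {}
    for pattern in motifs:
        rx = re.compile("(?=(" + _compile_motif(pattern) + "))")
        result[pattern] = [m.start() + 1 for m in rx.finditer(sequence)]
    return result


def check_gene_boundaries(gene_nt: str, config: ScreenConfig = ScreenConfig(),
                          allow_n: bool = False) -> tuple:
    """(has_start, has_stop) for the first and last codon of a gene.

    Non-ACGT characters raise; with ``allow_n`` an ambiguous N is tolerated
    and any codon containing it simply fails its membership test.
    """
    if len(gene_nt) < 6:
        raise ValueError("gene shorter than two codons")
    gene = gene_nt.upper()
    allowed = set("ACGTN") if allow_n else set("ACGT")
    bad = set(gene) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in gene: {sorted(bad)}")
    first, last = gene[:3], gene[-3:]
    return (first in config.start_codons, last in config.stop_codons)


def _needleman_wunsch(a: str, b: str) -> tuple:
    """Global alignment with match +1, mismatch 0, linear gap -1.

    Returns (identical_columns, alignment_length) for the traceback that
    prefers diagonal moves, then gaps in ``a``, then gaps in ``b``.
    """
    n, m = len(a), len(b)
    prev = list(range(0, -(m + 1), -1))
    # pointer codes: 0 diag, 1 up (gap in b), 2 left (gap in a)
    ptr = [[2] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        ptr[0][j] = 2
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        cur[0] = -i
        ptr[i][0] = 1
        ai = a[i - 1]
        row_ptr = ptr[i]
        prev_row = prev
        for j in range(1, m + 1):
            diag = prev_row[j - 1] + (1 if ai == b[j - 1] else 0)
            up = prev_row[j] - 1
            left = cur[j - 1] - 1
            best = diag
            code = 0
            if up > best:
                best, code = up, 1
            if left > best:
                best, code = left, 2
            cur[j] = best
            row_ptr[j] = code
        prev = cur
    ident = 0
    length = 0
    i, j = n, m
    while i > 0 or j > 0:
        code = ptr[i][j] if (i > 0 and j > 0) else (1 if i > 0 else 2)
        length += 1
        if code == 0:
            if a[i - 1] == b[j - 1]:
                ident += 1
            i -= 1
            j -= 1
        elif code == 1:
            i -= 1
        else:
            j -= 1
    return ident, length


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over the global-alignment length (gaps included).

    Scoring is match +1 / mismatch 0 / linear gap -1. The pair is ordered
    lexicographically before aligning so the result is symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if b < a:
        a, b = b, a
    ident, length = _needleman_wunsch(a, b)
    return 100.0 * ident / length


def dedup_candidates(proteins: Sequence[ProteinRecord], identity_cutoff: float = 90.0) -> list:
    """Greedy clustering at the identity cutoff; returns representative ids.

    Sequences are visited by descending length (ties broken by id); each
    joins the first representative at identity >= cutoff (inclusive) or
    founds a new cluster. Founders are the representatives.
    """
    if not (0.0 < identity_cutoff <= 100.0):
        raise ValueError("identity cutoff must be in (0, 100]")
    order = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    reps: list = []
    for p in order:
        for rep in reps:
            if pairwise_identity(p.sequence, rep.sequence) >= identity_cutoff:
                break
        else:
            reps.append(p)
    return [r.id for r in reps]


def filter_samples_by_environment(metadata: Sequence[SampleMetadata],
                                  config: ScreenConfig) -> set:
    """Sample ids at temperature >= minimum and, when required, alkaline pH."""
    kept = set()
    for m in metadata:
        if m.temperature < config.min_temperature:
            continue
        if config.require_alkaline and not m.pH > 7.0:
            continue
        kept.add(m.sample_id)
    return kept


# ---------------------------------------------------------------------------
# Full cascade


def compile_report(
    proteins: Sequence[ProteinRecord],
    domain_hits: Sequence[DomainHit],
    similarity_hits: Sequence[SimilarityHit],
    topology: Mapping[str, bool],
    metadata: Sequence[SampleMetadata],
    config: ScreenConfig = ScreenConfig(),
) -> list:
    """Run the full cascade and return one CandidateReport per protein.

    Steps, in order: branch assignment (SCAP first; proteins without a SCAP
    hit go to the fnr similarity branch), environment filter, motif scan,
    gene boundary check, length check, SP/TM flagging, greedy de-duplication
    among proteins passing everything else. A protein is selected when it has
    branch evidence, passes environment, carries all motifs, has valid start
    and stop codons, has plausible length, and is a cluster representative.
    ``topology`` maps protein id -> SP or TM predicted (missing ids mean no
    prediction). Row order of any input never affects the outcome.
    """
    known = {p.id for p in proteins}
    if len(known) != len(proteins):
        raise ValueError("duplicate protein ids")
    for h in domain_hits:
        if h.protein_id not in known:
            raise ReferentialIntegrityError(f"domain hit references unknown protein {h.protein_id!r}")
    for h in similarity_hits:
        if h.query_id not in known:
            raise ReferentialIntegrityError(f"similarity hit references unknown protein {h.query_id!r}")
    for pid in topology:
        if pid not in known:
            raise ReferentialIntegrityError(f"topology row references unknown protein {pid!r}")

    scap_ids = select_scap_hits(domain_hits, config)
    # fnr branch only receives SCAP non-hits (branch disjointness)
    fnr_ids = select_similarity_hits(
        [h for h in similarity_hits if h.query_id not in scap_ids], config
    )
    env_samples = filter_samples_by_environment(metadata, config)
    lo, hi = config.length_bounds

    prelim: list = []
    reports: dict = {}
    for p in sorted(proteins, key=lambda p: p.id):
        reasons = []
        branch = "scap" if p.id in scap_ids else ("fnr" if p.id in fnr_ids else None)
        if branch is None:
            reasons.append("no SCAP domain hit and no similarity hit at the e-value cutoff")

        env_ok = p.sample_id in env_samples
        if not env_ok:
            reasons.append(
                f"sample environment fails temperature >= {config.min_temperature} C"
                + (" / alkaline pH" if config.require_alkaline else "")
            )

        motif_hits = scan_motifs(p.sequence, config.motifs)
        motif_ok = all(motif_hits[m] for m in config.motifs)
        if not motif_ok:
            missing = [m for m in config.motifs if not motif_hits[m]]
            reasons.append(f"missing active-site motif(s): {', '.join(missing)}")

        if p.gene_nt is None:
            boundary = (False, False)
            reasons.append("no gene sequence available for boundary check")
        elif len(p.gene_nt) < 6:
            boundary = (False, False)
            reasons.append("gene shorter than two codons")
        else:
            boundary = check_gene_boundaries(p.gene_nt, config, allow_n=True)
            if p.start_truncated:
                boundary = (False, boundary[1])
            if p.end_truncated:
                boundary = (boundary[0], False)
            if not boundary[0]:
                reasons.append("gene lacks a valid start codon")
            if not boundary[1]:
                reasons.append("gene lacks a valid stop codon")

        length_ok = lo <= len(p.sequence) <= hi
        if not length_ok:
            reasons.append(
                f"length {len(p.sequence)} outside [{lo:.0f}, {hi:.0f}] residue window"
            )

        sp_or_tm = bool(topology.get(p.id, False))
        if sp_or_tm:
            reasons.append("signal peptide or transmembrane region predicted")

        passes = (
            branch is not None
            and env_ok
            and motif_ok
            and boundary[0]
            and boundary[1]
            and length_ok
            and not (config.sp_tm_policy == "reject" and sp_or_tm)
        )
        if passes:
            prelim.append(p)
        reports[p.id] = CandidateReport(
            protein_id=p.id,
            branch=branch,
            motif_hits=motif_hits,
            boundary_ok=boundary,
            length_ok=length_ok,
            sp_or_tm=sp_or_tm,
            env_ok=env_ok,
            cluster_representative=False,
            selected=False,
            reasons=reasons,
        )

    reps = set(dedup_candidates(prelim, config.identity_cutoff))
    for p in prelim:
        r = reports[p.id]
        r.cluster_representative = p.id in reps
        if p.id in reps:
            r.selected = True
        else:
            r.reasons.append(
                f"not a cluster representative at {config.identity_cutoff}% identity"
            )
    return [reports[pid] for pid in sorted(reports)]


def selected_ids(reports: Iterable[CandidateReport]) -> set:
    return {r.protein_id for r in reports if r.selected}
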