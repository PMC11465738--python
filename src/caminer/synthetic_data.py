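"""Seeded generators for every input the analysis modules consume.

The raw study inputs (metagenome assemblies, stopped-flow instrument traces,
reactor pressure logs) are not shippable, so each analysis module is
exercised against synthetic inputs with known ground truth:

* screening fixtures — predicted-protein sets with planted CA-like positives
  (both beta-CA motifs, valid gene boundaries, plausible length, hot alkaline
  source samples, SCAP-domain or similarity evidence) and decoys that each
  violate at least one selection criterion;
* stopped-flow traces — forward integration of CO2 hydration with proton
  release buffered by Tris plus phenol red, mapped to absorbance through the
  deprotonated-indicator fraction;
* residual-activity decay series — first-order decay with an optional
  transient "thermal activation" bump;
* reactor pressure curves — the pseudo-first-order absorption model plus
  gaussian gauge noise.

Every generator is bit-reproducible for a fixed seed. Amino-acid backgrounds
are uniform over the 20 standard residues; instrument noise is additive
gaussian and homoscedastic (magnitudes are defaults, not measured values,
and are plain arguments so they are easy to override).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .candidate_screen import (
    AMINO_ACIDS,
    DomainHit,
    ProteinRecord,
    SampleMetadata,
    ScreenConfig,
    SimilarityHit,
    scan_motifs,
)
from .reactor import ForwardParams, PressureSeries, ReactorConfig, simulate_pressure
from .stability import DecaySeries
from .stopped_flow import Trace

__all__ = [
    "ScreenFixture",
    "TraceSpec",
    "make_screen_fixture",
    "make_stopped_flow_trace",
    "make_decay_series",
    "make_pressure_curve",
    "make_mm_dataset",
]

_STOP_CODONS = ("TAA", "TGA", "TAG")
_NT = "ACGT"


# ---------------------------------------------------------------------------
# Screening fixture


@dataclass
class ScreenFixture:
    """A synthetic screening problem with its planted ground truth."""

    proteins: List[ProteinRecord]
    domain_table: List[DomainHit]
    similarity_table: List[SimilarityHit]
    topology_table: Dict[str, Tuple[bool, bool]]  # id -> (signal peptide, transmembrane)
    metadata: List[SampleMetadata]
    truth: set = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = {p.id for p in self.proteins}
        if not self.truth <= ids:
            raise ValueError("truth ids must exist among the proteins")
        for h in self.domain_table:
            if h.protein_id not in ids:
                raise ValueError(f"domain row references unknown protein {h.protein_id!r}")
        for h in self.similarity_table:
            if h.query_id not in ids:
                raise ValueError(f"similarity row references unknown protein {h.query_id!r}")

    @property
    def sp_tm_flags(self) -> Dict[str, bool]:
        return {pid: sp or tm for pid, (sp, tm) in self.topology_table.items()}

    def cascade_inputs(self) -> tuple:
        """Arguments for candidate_screen.compile_report."""
        return (self.proteins, self.domain_table, self.similarity_table,
                self.sp_tm_flags, self.metadata)

    def write(self, outdir) -> None:
        """Write all fixture components in their standard text formats."""
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_protein_fasta(outdir / "proteins.faa", self.proteins)
        cio.write_gene_fasta(outdir / "genes.fna", self.proteins)
        cio.write_domtbl(outdir / "domains.domtbl", self.domain_table)
        cio.write_blast_tab(outdir / "similarity.tsv", self.similarity_table)
        cio.write_phobius_short(outdir / "topology.txt", self.topology_table)
        cio.write_metadata_tsv(outdir / "metadata.tsv", self.metadata)
        (outdir / "truth.json").write_text(json.dumps(sorted(self.truth), indent=1))


def _rand_seq(rng: np.random.Generator, length: int) -> list:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)]


def _realize_motif(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))] if c == "x" else c for c in pattern
    )


def _insert_motifs(rng: np.random.Generator, seq: list, patterns: Sequence[str]) -> list:
    """Place each motif at a uniformly random offset, non-overlapping."""
    taken: list = []
    for pattern in patterns:
        w = len(pattern)
        for _ in range(200):
            pos = int(rng.integers(0, len(seq) - w + 1))
            if all(pos + w <= lo or pos >= hi for lo, hi in taken):
                break
        else:  # pragma: no cover - sequence long enough in practice
            raise RuntimeError("could not place motif without overlap")
        seq[pos:pos + w] = list(_realize_motif(rng, pattern))
        taken.append((pos, pos + w))
    return seq


def _scrub_motif(seq: list, pattern: str, protected: set = frozenset()) -> list:
    """Mutate the sequence until the motif no longer occurs anywhere.

    Each occurrence is destroyed by rewriting one of its literal positions to
    glycine (a residue appearing in no motif literal), never touching
    ``protected`` positions. Because wildcards match any residue, a
    substitution to G can only remove matches, so the loop terminates.
    """
    literal_offsets = [i for i, c in enumerate(pattern) if c != "x"]
    for _ in range(len(seq)):
        hits = scan_motifs("".join(seq), [pattern])[pattern]
        if not hits:
            return seq
        start = hits[0] - 1
        for off in literal_offsets:
            if start + off not in protected:
                seq[start + off] = "G"
                break
        else:  # pragma: no cover - motif wider than the protected span
            raise RuntimeError("motif occurrence entirely inside protected span")
    raise RuntimeError("failed to scrub motif")  # pragma: no cover


def _make_gene(rng: np.random.Generator, n_residues: int,
               good_start: bool = True, good_stop: bool = True) -> str:
    start = "ATG" if good_start else "CCT"
    stop = _STOP_CODONS[int(rng.integers(0, 3))] if good_stop else "CCT"
    middle = "".join(_NT[i] for i in rng.integers(0, 4, 3 * (n_residues - 1)))
    return start + middle + stop


_DECOY_KINDS = ("no_evidence", "no_motif", "bad_boundary", "bad_length",
                "bad_env", "near_duplicate")


def make_screen_fixture(n_proteins: int, n_positives: int, seed: int,
                        config: ScreenConfig = ScreenConfig()) -> ScreenFixture:
    """Generate a screening fixture with ``n_positives`` planted positives.

    Positives satisfy every cascade criterion; each decoy violates at least
    one, and with six or more decoys every criterion is violated by at least
    one decoy (no evidence, missing motif, bad gene boundaries, implausible
    length, wrong sampling environment, near-duplicate of a positive).
    Deterministic for a fixed seed.
    """
    if not (0 <= n_positives <= n_proteins):
        raise ValueError("need 0 <= n_positives <= n_proteins")
    rng = np.random.default_rng(seed)
    mean = config.family_mean_length

    samples = [
        SampleMetadata("hotspring_a", float(rng.uniform(90, 97)), float(rng.uniform(8.0, 9.5)),
                       "hot spring sediment, alkaline"),
        SampleMetadata("hotspring_b", float(rng.uniform(90, 97)), float(rng.uniform(8.0, 9.5)),
                       "geothermal outflow, alkaline"),
        SampleMetadata("temperate_soil", 25.0, 8.5, "temperate soil control"),
        SampleMetadata("acidic_vent", 95.0, 6.0, "acidic hydrothermal vent"),
    ]
    hot_ids = [samples[0].sample_id, samples[1].sample_id]
    bad_env_ids = [samples[2].sample_id, samples[3].sample_id]

    positive_idx = set(
        int(i) for i in rng.choice(n_proteins, size=n_positives, replace=False)
    )
    proteins: List[ProteinRecord] = []
    domain_table: List[DomainHit] = []
    similarity_table: List[SimilarityHit] = []
    topology: Dict[str, Tuple[bool, bool]] = {}
    truth: set = set()
    positives: List[ProteinRecord] = []

    def add_scap_hit(pid: str, length: int) -> None:
        domain_table.append(DomainHit(
            protein_id=pid, profile_accession="PF00484.21", profile_name="Pro_CA",
            i_evalue=float(10.0 ** rng.uniform(-60, -20)),
            bit_score=float(rng.uniform(80, 250)),
            env_from=1, env_to=min(100, length),
        ))

    def add_fnr_hit(pid: str, length: int, strong: bool) -> None:
        exponent = rng.uniform(-80, -55) if strong else rng.uniform(-45, -20)
        similarity_table.append(SimilarityHit(
            query_id=pid, subject_id=f"WP_{int(rng.integers(1e8, 1e9)):09d}.1",
            evalue=float(10.0 ** exponent),
            pct_identity=float(rng.uniform(40, 95)),
            subject_title="carbonic anhydrase [Thermophilus synthetica]",
            query_coverage=float(rng.uniform(70, 100)),
        ))

    n_pos_seen = 0
    n_decoys_seen = 0
    for i in range(n_proteins):
        pid = f"p{i:04d}"
        if i in positive_idx:
            k = n_pos_seen
            n_pos_seen += 1
            length = int(rng.integers(round(0.8 * mean), round(1.2 * mean) + 1))
            seq = _insert_motifs(rng, _rand_seq(rng, length), config.motifs)
            rec = ProteinRecord(
                id=pid, sequence="".join(seq),
                gene_nt=_make_gene(rng, length),
                sample_id=hot_ids[k % 2],
            )
            if k % 2 == 0:
                add_scap_hit(pid, length)
            else:
                add_fnr_hit(pid, length, strong=True)
            topology[pid] = (False, False)
            proteins.append(rec)
            positives.append(rec)
            truth.add(pid)
            continue

        kind = _DECOY_KINDS[n_decoys_seen % len(_DECOY_KINDS)]
        if kind == "near_duplicate" and not positives:
            kind = "no_evidence"
        n_decoys_seen += 1

        length = int(rng.integers(round(0.8 * mean), round(1.2 * mean) + 1))
        sample_id = hot_ids[i % 2]
        sp = False
        good_start, good_stop = True, True
        evidence = "scap" if n_decoys_seen % 2 else "fnr"

        if kind == "near_duplicate":
            src = positives[(n_decoys_seen // len(_DECOY_KINDS)) % len(positives)]
            seq = list(src.sequence[:-3])  # shorter, so the positive stays the founder
            protected = set()
            hits = scan_motifs("".join(seq), config.motifs)
            for pattern, starts in hits.items():
                for s in starts:
                    protected.update(range(s - 1, s - 1 + len(pattern)))
            n_mut = max(1, int(0.02 * len(seq)))
            free = [p for p in range(len(seq)) if p not in protected]
            for p in rng.choice(len(free), size=min(n_mut, len(free)), replace=False):
                pos = free[int(p)]
                choices = [a for a in AMINO_ACIDS if a != seq[pos]]
                seq[pos] = choices[int(rng.integers(0, len(choices)))]
            length = len(seq)
        else:
            seq = _rand_seq(rng, length)
            if kind == "no_motif":
                # retain the second motif, guarantee the first is absent
                for _attempt in range(50):
                    cand = _insert_motifs(rng, _rand_seq(rng, length), [config.motifs[1]])
                    kept = scan_motifs("".join(cand), [config.motifs[1]])[config.motifs[1]]
                    protected = {
                        p for s in kept for p in range(s - 1, s - 1 + len(config.motifs[1]))
                    }
                    try:
                        seq = _scrub_motif(cand, config.motifs[0], protected)
                        break
                    except RuntimeError:  # pragma: no cover - pathological overlap
                        continue
                sp = True  # also exercises the SP/TM flag (flag-only by default)
            else:
                seq = _insert_motifs(rng, seq, config.motifs)
            if kind == "bad_boundary":
                if n_decoys_seen % 2:
                    good_start = False
                else:
                    good_stop = False
            elif kind == "bad_length":
                length = int(0.3 * mean) if n_decoys_seen % 2 else int(2.5 * mean)
                seq = _insert_motifs(rng, _rand_seq(rng, length), config.motifs)
            elif kind == "bad_env":
                sample_id = bad_env_ids[n_decoys_seen % 2]

        rec = ProteinRecord(
            id=pid, sequence="".join(seq),
            gene_nt=_make_gene(rng, len(seq), good_start, good_stop),
            sample_id=sample_id,
        )
        if kind == "no_evidence":
            # a non-SCAP domain and a weak similarity hit: realistic noise rows
            domain_table.append(DomainHit(
                protein_id=pid, profile_accession="PF07690.19", profile_name="MFS_1",
                i_evalue=float(10.0 ** rng.uniform(-20, -5)),
                bit_score=float(rng.uniform(20, 60)), env_from=1, env_to=len(seq),
            ))
            add_fnr_hit(pid, len(seq), strong=False)
        elif evidence == "scap":
            add_scap_hit(pid, len(seq))
        else:
            add_fnr_hit(pid, len(seq), strong=True)
        topology[pid] = (sp, False)
        proteins.append(rec)

    return ScreenFixture(
        proteins=proteins,
        domain_table=domain_table,
        similarity_table=similarity_table,
        topology_table=topology,
        metadata=samples,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Stopped-flow trace


@dataclass(frozen=True)
class TraceSpec:
    """Forward-model parameters of one stopped-flow run (reaction cell).

    Defaults are the published assay conditions after 1:1 mixing: CA-KR1-like
    kinetics (kcat 1.2e3 1/s, KM 4.9 mM), 350 nM enzyme, CO2-saturated water
    (34 mM stock, 17 mM in cell), uncatalyzed hydration constant 3.5e-2 1/s,
    10 mM Tris (pKa 8.07), 0.1 mM phenol red (pKa 7.9), pH 8.3.
    """

    kcat: float = 1.2e3  # 1/s
    KM: float = 4.9e-3  # mol/L
    enzyme_conc: float = 350e-9  # mol/L
    co2_init: float = 17e-3  # mol/L in the reaction cell
    k_uncat: float = 3.5e-2  # 1/s
    buffer_total: float = 10e-3  # mol/L
    indicator_total: float = 0.1e-3  # mol/L
    buffer_pKa: float = 8.07
    indicator_pKa: float = 7.9
    epsilon_path: float = 1.0  # absorbance per mole fraction deprotonated
    pH_init: float = 8.3
    noise_sd: float = 0.002  # absorbance units
    seed: int = 0
    dt: float = 0.1  # s
    duration: float = 30.0  # s

    def __post_init__(self) -> None:
        for name in ("KM", "enzyme_conc", "co2_init", "buffer_total", "indicator_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if not (6.0 < self.pH_init < 10.0):
            raise ValueError("pH_init must lie in (6, 10)")


def _prot_total(pH: float, spec: TraceSpec) -> float:
    """Protonated buffer + indicator + free protons at a given pH (mol/L)."""
    fb = 1.0 / (1.0 + 10.0 ** (pH - spec.buffer_pKa))
    fi = 1.0 / (1.0 + 10.0 ** (pH - spec.indicator_pKa))
    return spec.buffer_total * fb + spec.indicator_total * fi + 10.0 ** (-pH)


def _ph_from_protons(h_released: float, spec: TraceSpec) -> float:
    """Invert proton conservation for pH; monotone, solved by bisection."""
    base = _prot_total(spec.pH_init, spec)

    def g(pH: float) -> float:
        return _prot_total(pH, spec) - base - h_released

    if h_released <= 0:
        return spec.pH_init
    lo = 0.3
    if g(lo) < 0:  # beyond total buffering capacity: pin at the floor
        return lo
    return float(brentq(g, lo, spec.pH_init, xtol=1e-12))


def make_stopped_flow_trace(spec: TraceSpec, return_truth: bool = False):
    """Simulate an absorbance trace; optionally return the noiseless truth.

    Integrates d[CO2]/dt = -(k_uncat + kcat*E/(KM+S))*S, accumulates released
    protons into the buffer/indicator Henderson-Hasselbalch equilibria, and
    maps the deprotonated-indicator mole fraction to absorbance through
    ``epsilon_path``. Gaussian noise of sd ``noise_sd`` is added per point.
    With ``return_truth`` the noiseless internals (CO2, pH, d[CO2]/dt,
    absorbance) are returned alongside the trace.
    """
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)

    def dSdt(_t, y):
        S = max(y[0], 0.0)
        return [-(spec.k_uncat + spec.kcat * spec.enzyme_conc / (spec.KM + S)) * S]

    sol = solve_ivp(dSdt, (0.0, float(t[-1])), [spec.co2_init], t_eval=t,
                    rtol=1e-10, atol=1e-14, method="RK45")
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"CO2 integration failed: {sol.message}")
    S = np.clip(sol.y[0], 0.0, spec.co2_init)
    h_released = spec.co2_init - S
    pH = np.array([_ph_from_protons(float(h), spec) for h in h_released])
    f_deprot = 1.0 - 1.0 / (1.0 + 10.0 ** (pH - spec.indicator_pKa))
    absorbance = spec.epsilon_path * f_deprot
    dS = -(spec.k_uncat + spec.kcat * spec.enzyme_conc / (spec.KM + S)) * S

    rng = np.random.default_rng(spec.seed)
    noisy = absorbance + rng.normal(0.0, spec.noise_sd, size=absorbance.size) \
        if spec.noise_sd > 0 else absorbance.copy()
    trace = Trace(time=t, absorbance=noisy)
    if not return_truth:
        return trace
    truth = {"time": t, "co2": S, "pH": pH, "dco2_dt": dS, "absorbance": absorbance}
    return trace, truth


# ---------------------------------------------------------------------------
# Initial-rate datasets (Michaelis-Menten)


def make_mm_dataset(kcat: float, KM: float, enzyme_conc: float,
                    substrate: Sequence[float], noise_frac: float = 0.03,
                    replicates: int = 3, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Initial CO2-hydration rates from the Michaelis-Menten model.

    Returns (substrate, rate) arrays with ``replicates`` noisy measurements
    per substrate level; noise is multiplicative gaussian with relative sd
    ``noise_frac``. Units mol/L and mol/(L*s).
    """
    rng = np.random.default_rng(seed)
    S = np.repeat(np.asarray(substrate, dtype=float), replicates)
    v_true = kcat * enzyme_conc * S / (KM + S)
    v = v_true * (1.0 + noise_frac * rng.standard_normal(S.size))
    return S, np.clip(v, 0.0, None)


# ---------------------------------------------------------------------------
# Decay series


def make_decay_series(half_life: float, timepoints: Sequence[float],
                      activation_bump: float = 0.0, noise_sd: float = 0.0,
                      seed: int = 0) -> DecaySeries:
    """First-order residual-activity decay, optional activation bump, noise.

    residual(t) = 100 * 2^(-t/half_life), multiplied (when activation_bump
    > 0) by a transient rise peaking at the second timepoint with relative
    amplitude ``activation_bump`` and vanishing at t = 0 — emulating the
    thermal-activation profile of thermophilic enzymes. ``noise_sd`` is a
    fraction of the initial value (0.05 = 5 percentage points). The series
    is renormalized so the t = 0 point reads exactly 100%.
    """
    if half_life <= 0:
        raise ValueError("half-life must be positive")
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0) or not np.all(np.diff(t) > 0):
        raise ValueError("timepoints must be non-negative and sorted")
    base = 100.0 * 2.0 ** (-t / half_life)
    if activation_bump > 0 and t.size > 1 and t[1] > 0:
        x = t / t[1]
        base = base * (1.0 + activation_bump * x * np.exp(1.0 - x))
    rng = np.random.default_rng(seed)
    raw = base + 100.0 * noise_sd * rng.standard_normal(t.size) if noise_sd > 0 else base
    if raw[0] <= 0:  # pragma: no cover - would need extreme noise
        raise RuntimeError("noise destroyed the reference point")
    residual = 100.0 * raw / raw[0]
    return DecaySeries(timepoints=t, residual=residual)


# ---------------------------------------------------------------------------
# Reactor pressure curves


def make_pressure_curve(config: ReactorConfig, params: ForwardParams,
                        t_grid: Sequence[float], noise_sd_bar: float = 0.0,
                        seed: int = 0) -> PressureSeries:
    """Simulated reactor pressure log with gaussian gauge noise (sd in bar)."""
    clean = simulate_pressure(config, params, np.asarray(t_grid, dtype=float))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_bar * 1e5, size=clean.pressure.size) \
        if noise_sd_bar > 0 else 0.0
    return PressureSeries(time=clean.time, pressure=clean.pressure + noise)
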