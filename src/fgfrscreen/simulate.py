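"""Seeded generators for call sets and viability plates.

The study this package models deposited no raw data, so every analysis stage
is exercised on synthetic inputs that reproduce the *statistical structure*
the pipeline assumes: binomially sampled alt reads at negative-binomial
amplicon depths, caller-specific detection floors and false positives,
recurrent low-VAF amplification artifacts shared across samples,
run-restricted batch artifacts, germline-like high-prevalence variants, and
Hill-shaped viability curves with an FGF2-induced IC50 shift that an FGFR
inhibitor reverses.

:func:`scenario_study` bundles the packaged worked-example scenario: a
481-sample primary cohort (plus 28 relapse and 12 cell-line samples) whose
truth table injects the four reported FGFR variants alongside >=200 decoys,
and an eight-line viability panel with five FGF2-responsive lines.

The synthetic FGFR1/2/3 transcript models are built with a fixed internal
seed, so gene coordinates and the four variant keys are stable across runs;
the user-supplied seed drives every stochastic draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotate import TranscriptModel, load_domains, load_hotspots
from .variants import ConfigurationError, FilterConfig, Reason, ReferenceWindow, VariantKey

__all__ = [
    "CallerModel",
    "SomaticTruth",
    "ArtifactTruth",
    "RunArtifactTruth",
    "GermlineTruth",
    "CallSimConfig",
    "PlateLine",
    "PlateSimConfig",
    "SimulatedCalls",
    "SimulatedPlates",
    "ScenarioBundle",
    "simulate_callsets",
    "simulate_plates",
    "scenario_study",
    "build_synthetic_fgfr_models",
]

_MODEL_SEED = 20160  # fixed: gene models are scenario assets, not random draws
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Synthetic FGFR gene models


@dataclass
class GeneAssets:
    model: TranscriptModel
    reference: ReferenceWindow
    targets: list[tuple[int, int]]  # 0-based half-open, exon +/- flank


def _build_gene(
    rng: np.random.Generator,
    gene: str,
    n_codons: int,
    chrom: str,
    offset: int,
    strand: str,
    n_exons: int,
    pinned: dict[int, str],
    intron_len: int = 200,
    outer_flank: int = 300,
    target_flank: int = 50,
) -> GeneAssets:
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)
    ]
    for codon_1based, triplet in pinned.items():
        codons[codon_1based - 1] = triplet
    cds = "".join(codons)

    cuts = np.linspace(0, len(cds), n_exons + 1).round().astype(int)
    chunk_lens = np.diff(cuts)
    # transcript-order chunks; genomic order is reversed on the minus strand
    chunks = [cds[cuts[i] : cuts[i + 1]] for i in range(n_exons)]
    genomic_chunks = (
        chunks if strand == "+" else [c.translate(_COMPLEMENT)[::-1] for c in chunks[::-1]]
    )

    def rand_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    pieces = [rand_seq(outer_flank)]
    segments: list[tuple[int, int]] = []
    cursor = offset + outer_flank  # 1-based start of next exon
    for i, chunk in enumerate(genomic_chunks):
        segments.append((cursor, cursor + len(chunk) - 1))
        pieces.append(chunk)
        cursor += len(chunk)
        if i < n_exons - 1:
            pieces.append(rand_seq(intron_len))
            cursor += intron_len
    pieces.append(rand_seq(outer_flank))
    sequence = "".join(pieces)

    model = TranscriptModel(gene, chrom, strand, segments, cds)
    reference = ReferenceWindow(chrom, offset, sequence)
    targets = [(s - 1 - target_flank, e + target_flank) for s, e in segments]
    assert sum(chunk_lens) == len(cds)
    return GeneAssets(model=model, reference=reference, targets=targets)


def build_synthetic_fgfr_models() -> dict[str, GeneAssets]:
    """Deterministic synthetic FGFR1/2/3 transcript models.

    Protein lengths match the human receptors (822/821/806 aa); the codons
    carrying the screen's variants of interest (FGFR1 129, FGFR2 274 and
    522, FGFR3 384) are pinned to the wild-type triplets so the expected
    amino-acid changes exist at stable genomic keys.  FGFR2 is placed on the
    minus strand to exercise orientation handling.
    """
    rng = np.random.default_rng(_MODEL_SEED)
    return {
        "FGFR1": _build_gene(rng, "FGFR1", 822, "8", 38_000_000, "+", 5, {129: "GAC"}),
        "FGFR2": _build_gene(
            rng, "FGFR2", 821, "10", 123_000_000, "-", 5, {274: "GTC", 522: "GAC"}
        ),
        "FGFR3": _build_gene(rng, "FGFR3", 806, "4", 1_800_000, "+", 4, {384: "TTC"}),
    }


def key_for_cds_change(model: TranscriptModel, cds_index: int, alt_base: str) -> VariantKey:
    """Genomic :class:`VariantKey` realizing a transcript-strand substitution
    at 0-based CDS index ``cds_index``."""
    ref_t = model.cds_sequence[cds_index]
    if ref_t == alt_base:
        raise ValueError("alt equals reference base")
    pos = model.cds_to_genomic(cds_index)
    if model.strand == "-":
        return VariantKey(model.chrom, pos, ref_t.translate(_COMPLEMENT), alt_base.translate(_COMPLEMENT))
    return VariantKey(model.chrom, pos, ref_t, alt_base)


# ---------------------------------------------------------------------------
# Call-set simulation


@dataclass(frozen=True)
class CallerModel:
    name: str
    detection_floor: int = 2  # min alt reads to report a site
    fp_rate: float = 0.0  # false positives per target base per sample


@dataclass(frozen=True)
class SomaticTruth:
    sample: str
    key: VariantKey
    vaf: float
    depth: int
    restrict_callers: Optional[tuple[str, ...]] = None
    label: str = "somatic"
    expected_reason: str = ""


@dataclass(frozen=True)
class ArtifactTruth:
    key: VariantKey
    n_carriers: int
    vaf_range: tuple[float, float]
    depth: Optional[int] = None


@dataclass(frozen=True)
class RunArtifactTruth:
    key: VariantKey
    run: str
    n_carriers: int
    vaf_range: tuple[float, float]
    depth: Optional[int] = None


@dataclass(frozen=True)
class GermlineTruth:
    key: VariantKey
    population_freq: float  # carrier probability per sample
    in_snp_list: bool


@dataclass
class CallSimConfig:
    samples: list[tuple[str, str]]  # (sample id, cohort label)
    n_runs: int
    callers: list[CallerModel]
    somatic_truth: list[SomaticTruth] = field(default_factory=list)
    artifact_truth: list[ArtifactTruth] = field(default_factory=list)
    run_artifact_truth: list[RunArtifactTruth] = field(default_factory=list)
    germline_truth: list[GermlineTruth] = field(default_factory=list)
    depth_mean: float = 1000.0
    depth_dispersion: float = 100.0  # gamma shape; larger = tighter depths
    fp_vaf_range: tuple[float, float] = (0.001, 0.05)
    targets: Optional[dict[str, list[tuple[int, int]]]] = None
    reference: Optional[dict[str, ReferenceWindow]] = None
    seed: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    def validate(self) -> None:
        ids = set(self.sample_ids)
        if len(ids) != len(self.samples):
            raise ConfigurationError("duplicate sample ids")
        for item in self.somatic_truth:
            if item.sample not in ids:
                raise ConfigurationError(f"truth references unknown sample {item.sample!r}")
            if not 0.0 <= item.vaf <= 1.0:
                raise ConfigurationError("truth VAF outside [0, 1]")
        for item in self.artifact_truth:
            if item.n_carriers > len(self.samples):
                raise ConfigurationError("artifact carriers exceed cohort size")
        if self.n_runs < 1:
            raise ConfigurationError("need at least one run")


@dataclass
class SimulatedCalls:
    calls: pd.DataFrame  # sample, caller, chrom, pos, ref, alt, depth, alt_depth, run
    manifest: pd.DataFrame  # sample, cohort, run, subtype
    truth: pd.DataFrame  # label, sample, chrom, pos, ref, alt, true_vaf, expected_reason


def _runs_round_robin(n_samples: int, n_runs: int) -> list[str]:
    return [f"run{1 + i % n_runs}" for i in range(n_samples)]


def simulate_callsets(cfg: CallSimConfig) -> SimulatedCalls:
    """Simulate per-caller call tables for a cohort.

    For every truth occurrence a site-level expected depth is drawn from a
    gamma-Poisson (negative binomial) model around its nominal depth; each
    caller observes its own Poisson depth and binomial alt count and reports
    the site iff the alt count reaches its detection floor.  Caller-specific
    false positives are injected uniformly over the target footprint at
    VAF ~ U(fp_vaf_range), never colliding with a designed truth slot or
    with another caller's false positive at the same (sample, position).
    Identical seeds give identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    run_of = dict(zip(cfg.sample_ids, _runs_round_robin(len(cfg.samples), cfg.n_runs)))

    manifest = pd.DataFrame(
        {
            "sample": cfg.sample_ids,
            "cohort": [c for _, c in cfg.samples],
            "run": [run_of[s] for s in cfg.sample_ids],
            "subtype": "NA",
        }
    )

    # expand cohort-level truth into per-sample occurrences
    occurrences: list[tuple[str, VariantKey, float, float, Optional[tuple[str, ...]], str, str]] = []
    for item in cfg.somatic_truth:
        occurrences.append(
            (item.sample, item.key, item.vaf, item.depth, item.restrict_callers,
             item.label, item.expected_reason)
        )
    for item in cfg.artifact_truth:
        carriers = rng.choice(len(cfg.samples), size=item.n_carriers, replace=False)
        for idx in sorted(carriers):
            vaf = float(rng.uniform(*item.vaf_range))
            occurrences.append(
                (cfg.sample_ids[idx], item.key, vaf, item.depth or cfg.depth_mean,
                 None, "artifact", Reason.RECURRENT_ARTIFACT)
            )
    for item in cfg.run_artifact_truth:
        pool = [i for i, s in enumerate(cfg.sample_ids) if run_of[s] == item.run]
        if item.n_carriers > len(pool):
            raise ConfigurationError(f"run {item.run!r} has fewer samples than carriers")
        carriers = rng.choice(pool, size=item.n_carriers, replace=False)
        for idx in sorted(carriers):
            vaf = float(rng.uniform(*item.vaf_range))
            occurrences.append(
                (cfg.sample_ids[idx], item.key, vaf, item.depth or cfg.depth_mean,
                 None, "run_artifact", Reason.RUN_BIAS)
            )
    for item in cfg.germline_truth:
        hits = rng.random(len(cfg.samples)) < item.population_freq
        reason = Reason.KNOWN_SNP if item.in_snp_list else Reason.LIKELY_GERMLINE
        label = "known_snp" if item.in_snp_list else "germline"
        for idx in np.flatnonzero(hits):
            occurrences.append(
                (cfg.sample_ids[idx], item.key, 0.5, cfg.depth_mean, None, label, reason)
            )

    call_rows = []
    truth_rows = []
    occupied: set[tuple[str, str, int]] = set()
    shape = cfg.depth_dispersion
    for sample, key, vaf, depth_nominal, allowed, label, expected in occurrences:
        occupied.add((sample, key.chrom, key.pos))
        site_depth = rng.gamma(shape, depth_nominal / shape)
        callers = cfg.callers if allowed is None else [
            c for c in cfg.callers if c.name in allowed
        ]
        for caller in cfg.callers:
            depth = max(1, int(rng.poisson(site_depth)))
            alt = int(rng.binomial(depth, vaf))
            if caller not in callers or alt < caller.detection_floor:
                continue
            call_rows.append(
                (sample, caller.name, key.chrom, key.pos, key.ref, key.alt,
                 depth, alt, run_of[sample])
            )
        truth_rows.append(
            (label, sample, key.chrom, key.pos, key.ref, key.alt, vaf, expected)
        )

    # caller-specific false positives over the target footprint
    if cfg.targets and cfg.reference:
        flat_targets = [
            (chrom, pos)
            for chrom, ivals in sorted(cfg.targets.items())
            for start0, end0 in ivals
            for pos in range(start0 + 1, end0 + 1)
        ]
        n_bases = len(flat_targets)
        for caller in cfg.callers:
            n_fp = rng.poisson(caller.fp_rate * n_bases * len(cfg.samples))
            for _ in range(n_fp):
                sample = cfg.sample_ids[int(rng.integers(len(cfg.samples)))]
                chrom, pos = flat_targets[int(rng.integers(n_bases))]
                if (sample, chrom, pos) in occupied:
                    continue
                occupied.add((sample, chrom, pos))
                ref = cfg.reference[chrom].base_at(pos)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                vaf = float(rng.uniform(*cfg.fp_vaf_range))
                depth = max(1, int(rng.poisson(rng.gamma(shape, cfg.depth_mean / shape))))
                alt_depth = int(rng.binomial(depth, vaf))
                if alt_depth < caller.detection_floor:
                    continue
                call_rows.append(
                    (sample, caller.name, chrom, pos, ref, alt, depth, alt_depth,
                     run_of[sample])
                )
                truth_rows.append(
                    ("caller_fp", sample, chrom, pos, ref, alt, vaf, Reason.ONE_CALLER)
                )

    calls = pd.DataFrame(
        call_rows,
        columns=["sample", "caller", "chrom", "pos", "ref", "alt", "depth", "alt_depth", "run"],
    ).sort_values(["sample", "caller", "chrom", "pos", "alt"], kind="mergesort", ignore_index=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=["label", "sample", "chrom", "pos", "ref", "alt", "true_vaf", "expected_reason"],
    ).sort_values(["label", "sample", "chrom", "pos", "alt"], kind="mergesort", ignore_index=True)
    return SimulatedCalls(calls=calls, manifest=manifest, truth=truth)


# ---------------------------------------------------------------------------
# Viability-plate simulation


@dataclass(frozen=True)
class PlateLine:
    name: str
    true_ic50: float  # µg/mL, CTRL condition
    hill_slope: float = 1.5
    baseline: float = 0.1  # survival floor B of the Hill model
    fgf2_fold: float = 1.0  # IC50 multiplier under FGF2
    azd_reversal: bool = False  # AZD4547 restores the CTRL IC50
    fgf2_kill: float = 0.0  # single-agent kill fractions
    azd_kill: float = 0.0

    def __post_init__(self) -> None:
        if self.true_ic50 <= 0 or self.hill_slope <= 0:
            raise ConfigurationError("true_ic50 and hill_slope must be positive")
        if not 0.0 <= self.baseline < 0.5:
            raise ConfigurationError("baseline must be in [0, 0.5)")


@dataclass
class PlateSimConfig:
    cell_lines: list[PlateLine]
    doses: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.008, 250.0, 6)
    )  # six-step series, 250 down to 0.008 µg/mL
    n_replicates: int = 4
    noise_sd: float = 0.04  # Gaussian, survival scale, truncated at 0
    untreated_level: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise ConfigurationError("noise_sd >= 0 and n_replicates >= 1 required")
        if np.any(np.diff(self.doses) <= 0):
            raise ConfigurationError("doses must be strictly increasing")


@dataclass
class SimulatedPlates:
    plates: pd.DataFrame  # cell_line, condition, dose_ug_per_ml, replicate, signal
    truth: pd.DataFrame


def _hill(d: np.ndarray, ic50: float, h: float, baseline: float) -> np.ndarray:
    return baseline + (1.0 - baseline) / (1.0 + (d / ic50) ** h)


def simulate_plates(cfg: PlateSimConfig) -> SimulatedPlates:
    """Simulate an MTS/MTT viability panel.

    Survival follows ``S(d) = B + (1-B) / (1 + (d/IC50_c)^h)`` where the
    condition IC50 is shifted by ``fgf2_fold`` under FGF2 and restored under
    FGF2+AZD when the line's resistance is reversible.  Raw signal is
    ``untreated_level × (1 - kill_cond) × S(d)`` plus truncated Gaussian
    noise; kill fractions of co-exposed modulators combine independently.
    Dose-0 rows are each condition's drug-free control; UNTREATED rows carry
    neither drug nor modulator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    truth_rows = []

    def emit(line: str, condition: str, dose: float, mean_signal: float) -> None:
        for rep in range(cfg.n_replicates):
            signal = max(0.0, mean_signal + rng.normal(0.0, cfg.noise_sd * cfg.untreated_level))
            rows.append((line, condition, dose, rep + 1, signal))

    for line in cfg.cell_lines:
        kills = {
            "CTRL": 0.0,
            "FGF2": line.fgf2_kill,
            "AZD": line.azd_kill,
            "FGF2_AZD": 1.0 - (1.0 - line.fgf2_kill) * (1.0 - line.azd_kill),
        }
        ic50s = {
            "CTRL": line.true_ic50,
            "FGF2": line.true_ic50 * line.fgf2_fold,
            "AZD": line.true_ic50,
            "FGF2_AZD": line.true_ic50 * (1.0 if line.azd_reversal else line.fgf2_fold),
        }
        emit(line.name, "UNTREATED", 0.0, cfg.untreated_level)
        for condition in ("CTRL", "FGF2", "AZD", "FGF2_AZD"):
            level = cfg.untreated_level * (1.0 - kills[condition])
            emit(line.name, condition, 0.0, level)
            survival = _hill(cfg.doses, ic50s[condition], line.hill_slope, line.baseline)
            for dose, s in zip(cfg.doses, survival):
                emit(line.name, condition, float(dose), level * float(s))
        truth_rows.append(
            (line.name, line.true_ic50, line.hill_slope, line.baseline,
             line.fgf2_fold, line.azd_reversal, line.fgf2_kill, line.azd_kill)
        )

    plates = pd.DataFrame(
        rows, columns=["cell_line", "condition", "dose_ug_per_ml", "replicate", "signal"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["cell_line", "true_ic50", "hill_slope", "baseline", "fgf2_fold",
                 "azd_reversal", "fgf2_kill", "azd_kill"],
    )
    return SimulatedPlates(plates=plates, truth=truth)


# ---------------------------------------------------------------------------
# Packaged worked-example scenario


@dataclass
class ScenarioBundle:
    models: dict[str, TranscriptModel]
    reference: dict[str, ReferenceWindow]
    targets: dict[str, list[tuple[int, int]]]
    snp_list: set[VariantKey]
    domains: pd.DataFrame
    hotspots: pd.DataFrame
    filter_config: FilterConfig
    call_config: CallSimConfig
    plate_config: PlateSimConfig
    somatic_keys: dict[str, VariantKey]  # protein-change label -> key


def _pick_substitutions(
    rng: np.random.Generator,
    model: TranscriptModel,
    n: int,
    synonymous: bool,
    reserved_codons: set[int],
    used: set[VariantKey],
) -> list[VariantKey]:
    """Random coding substitutions of the requested consequence class."""
    out: list[VariantKey] = []
    n_codons = model.n_codons
    while len(out) < n:
        codon_i = int(rng.integers(1, n_codons))  # skip the start codon
        if codon_i + 1 in reserved_codons:
            continue
        offset = int(rng.integers(3))
        cds_i = 3 * codon_i + offset
        ref_t = model.cds_sequence[cds_i]
        codon = model.cds_sequence[3 * codon_i : 3 * codon_i + 3]
        alts = [b for b in "ACGT" if b != ref_t]
        rng.shuffle(alts)
        for alt_t in alts:
            mutant = codon[:offset] + alt_t + codon[offset + 1 :]
            if "*" in str(Seq(mutant).translate()):
                continue
            is_syn = str(Seq(mutant).translate()) == str(Seq(codon).translate())
            if is_syn != synonymous:
                continue
            key = key_for_cds_change(model, cds_i, alt_t)
            if key not in used:
                used.add(key)
                out.append(key)
            break
    return out


def _pick_positions(
    rng: np.random.Generator,
    candidates: list[tuple[str, int]],
    n: int,
    reference: dict[str, ReferenceWindow],
    used: set[VariantKey],
) -> list[VariantKey]:
    out: list[VariantKey] = []
    while len(out) < n:
        chrom, pos = candidates[int(rng.integers(len(candidates)))]
        ref = reference[chrom].base_at(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        key = VariantKey(chrom, pos, ref, alt)
        if key not in used:
            used.add(key)
            out.append(key)
    return out


def scenario_study(seed: int = 17) -> ScenarioBundle:
    """The packaged worked-example scenario.

    481 primary + 28 relapse + 12 cell-line samples over two sequencing
    runs.  Somatic truth injects the four reported variants — FGFR1 D129A
    (VAF 0.285), FGFR2 V274I (0.408), FGFR2 D522N (0.084), FGFR3 F384I
    (0.529), depth 1000 — into four distinct primary samples, alongside 240
    distinct decoy variants spanning every failure reason of the cascade.
    The viability panel has eight lines, five carrying a reversible 2.5-fold
    FGF2-induced IC50 shift.
    """
    assets = build_synthetic_fgfr_models()
    models = {g: a.model for g, a in assets.items()}
    reference = {a.model.chrom: a.reference for a in assets.values()}
    targets = {a.model.chrom: a.targets for a in assets.values()}
    rng = np.random.default_rng(seed)

    samples = (
        [(f"P{i:04d}", "primary") for i in range(1, 482)]
        + [(f"R{i:04d}", "relapse") for i in range(1, 29)]
        + [(f"CL{i:02d}", "cell_line") for i in range(1, 13)]
    )
    sample_ids = [s for s, _ in samples]
    primary_ids = [s for s, c in samples if c == "primary"]

    # --- the four reported somatic variants, at stable genomic keys
    fgfr1, fgfr2, fgfr3 = models["FGFR1"], models["FGFR2"], models["FGFR3"]
    somatic_keys = {
        "FGFR1 D129A": key_for_cds_change(fgfr1, 3 * 128 + 1, "C"),  # GAC->GCC
        "FGFR2 V274I": key_for_cds_change(fgfr2, 3 * 273 + 0, "A"),  # GTC->ATC
        "FGFR2 D522N": key_for_cds_change(fgfr2, 3 * 521 + 0, "A"),  # GAC->AAC
        "FGFR3 F384I": key_for_cds_change(fgfr3, 3 * 383 + 0, "A"),  # TTC->ATC
    }
    somatic_vafs = {
        "FGFR1 D129A": 0.285,
        "FGFR2 V274I": 0.408,
        "FGFR2 D522N": 0.084,
        "FGFR3 F384I": 0.529,
    }
    carriers = rng.choice(len(primary_ids), size=4, replace=False)
    somatic_truth = [
        SomaticTruth(primary_ids[idx], somatic_keys[name], somatic_vafs[name], 1000)
        for idx, name in zip(carriers, somatic_keys)
    ]

    used: set[VariantKey] = set(somatic_keys.values())
    reserved = {
        "FGFR1": {129},
        "FGFR2": {274, 522},
        "FGFR3": {384},
    }
    hotspots = load_hotspots()
    for gene, grp in hotspots.groupby("gene"):
        reserved[gene] |= set(int(c) for c in grp["codon"])

    def nonsyn(n: int) -> list[VariantKey]:
        per_gene = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
        keys = []
        for count, gene in zip(per_gene, ("FGFR1", "FGFR2", "FGFR3")):
            keys += _pick_substitutions(rng, models[gene], count, False, reserved[gene], used)
        return keys

    def syn(n: int) -> list[VariantKey]:
        return _pick_substitutions(rng, fgfr1, n, True, reserved["FGFR1"], used)

    # known SNPs: the reported FGFR3 F384L plus one synthetic FGFR2 entry
    snp_f384l = key_for_cds_change(fgfr3, 3 * 383 + 0, "C")  # TTC->CTC
    used.add(snp_f384l)
    snp_extra = _pick_substitutions(rng, fgfr2, 1, False, reserved["FGFR2"], used)[0]
    snp_list = {snp_f384l, snp_extra}

    # intronic-but-in-target and off-target candidate positions
    intronic: list[tuple[str, int]] = []
    offtarget: list[tuple[str, int]] = []
    for a in assets.values():
        chrom = a.model.chrom
        segs = a.model.cds_segments
        for (s1, e1), (s2, _) in zip(segs[:-1], segs[1:]):
            intronic += [(chrom, p) for p in range(e1 + 5, e1 + 45)]
            intronic += [(chrom, p) for p in range(s2 - 45, s2 - 5)]
        win = a.reference
        offtarget += [(chrom, p) for p in range(win.start + 20, segs[0][0] - 120)]
        offtarget += [(chrom, p) for p in range(segs[-1][1] + 120, win.end - 20)]

    # --- designed decoys, each violating one cascade rule
    truth: list[SomaticTruth] = list(somatic_truth)
    caller_names = ("freebayes", "varscan", "bcftools", "gatk")

    def rand_sample() -> str:
        return sample_ids[int(rng.integers(len(sample_ids)))]

    for key in nonsyn(50):  # reported by a single caller
        truth.append(
            SomaticTruth(rand_sample(), key, 0.25, 1000,
                         restrict_callers=(str(rng.choice(caller_names)),),
                         label="one_caller", expected_reason=Reason.ONE_CALLER)
        )
    for key in nonsyn(50):  # coverage below 100 reads
        truth.append(
            SomaticTruth(rand_sample(), key, 0.50, 60,
                         label="low_coverage", expected_reason=Reason.LOW_COVERAGE)
        )
    for key in nonsyn(50):  # fewer than 20 alt reads
        truth.append(
            SomaticTruth(rand_sample(), key, 0.010, 800,
                         label="low_alt_reads", expected_reason=Reason.LOW_ALT_READS)
        )
    for key in syn(25):
        truth.append(
            SomaticTruth(rand_sample(), key, 0.30, 1000,
                         label="synonymous", expected_reason=Reason.SYNONYMOUS)
        )
    for key in _pick_positions(rng, intronic, 25, reference, used):
        truth.append(
            SomaticTruth(rand_sample(), key, 0.30, 1000,
                         label="non_coding", expected_reason=Reason.NON_CODING)
        )
    for key in _pick_positions(rng, offtarget, 25, reference, used):
        truth.append(
            SomaticTruth(rand_sample(), key, 0.30, 1000,
                         label="off_target", expected_reason=Reason.OFF_TARGET)
        )

    artifact_truth = [
        ArtifactTruth(key, n_carriers=12, vaf_range=(0.009, 0.013), depth=4000)
        for key in nonsyn(8)
    ]
    run_artifact_truth = [
        RunArtifactTruth(key, run="run1", n_carriers=25, vaf_range=(0.08, 0.12), depth=1000)
        for key in nonsyn(3)
    ]
    germline_truth = [
        GermlineTruth(snp_f384l, population_freq=0.02, in_snp_list=True),
        GermlineTruth(snp_extra, population_freq=0.02, in_snp_list=True),
        GermlineTruth(nonsyn(1)[0], population_freq=0.18, in_snp_list=False),
        GermlineTruth(nonsyn(1)[0], population_freq=0.18, in_snp_list=False),
    ]

    call_config = CallSimConfig(
        samples=samples,
        n_runs=2,
        callers=[
            CallerModel("freebayes", detection_floor=2, fp_rate=2e-5),
            CallerModel("varscan", detection_floor=3, fp_rate=2e-5),
            CallerModel("bcftools", detection_floor=4, fp_rate=2e-5),
            CallerModel("gatk", detection_floor=5, fp_rate=2e-5),
        ],
        somatic_truth=truth,
        artifact_truth=artifact_truth,
        run_artifact_truth=run_artifact_truth,
        germline_truth=germline_truth,
        depth_mean=1000.0,
        depth_dispersion=100.0,
        targets=targets,
        reference=reference,
        seed=(seed * 2_654_435_761 + 1) % (2**31),
    )

    responsive = {"Nalm6", "697", "RCH-ACV", "Tom1", "MHH-CALL3"}
    line_params = [
        ("Nalm6", 1.2, 1.6, 0.30),
        ("697", 0.6, 1.4, 0.05),
        ("RCH-ACV", 2.5, 1.8, 0.25),
        ("Tom1", 0.9, 1.2, 0.05),
        ("MHH-CALL3", 1.8, 1.5, 0.05),
        ("SupB15", 1.0, 1.5, 0.05),
        ("MHH-CALL2", 2.0, 1.3, 0.05),
        ("MHH-CALL4", 0.8, 1.7, 0.05),
    ]
    plate_config = PlateSimConfig(
        cell_lines=[
            PlateLine(
                name=name,
                true_ic50=ic50,
                hill_slope=h,
                baseline=0.1,
                fgf2_fold=2.5 if name in responsive else 1.0,
                azd_reversal=name in responsive,
                fgf2_kill=0.05,
                azd_kill=azd_kill,
            )
            for name, ic50, h, azd_kill in line_params
        ],
        n_replicates=4,
        noise_sd=0.04,
        seed=(seed * 2_246_822_519 + 2) % (2**31),
    )

    return ScenarioBundle(
        models=models,
        reference=reference,
        targets=targets,
        snp_list=snp_list,
        domains=load_domains(),
        hotspots=hotspots,
        filter_config=FilterConfig(),
        call_config=call_config,
        plate_config=plate_config,
        somatic_keys=somatic_keys,
    )
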