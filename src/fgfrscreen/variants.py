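"""Multi-caller consensus merging and the amplicon-screen filter cascade.

The screen accepts per-(sample, caller) variant calls from a deep targeted
amplicon experiment, merges them into per-sample consensus calls, and applies
a cascade of site-level and cohort-level filters:

* site level — minimum caller agreement, coverage, and alt-read support;
* cohort level — recurrent low-VAF amplification artifacts (same change in
  ``n >= artifact_min_samples`` samples, each below ``artifact_max_vaf``) and
  sequencing-run bias (exact test on the run × carrier table);
* biological — synonymous / non-coding changes, known SNPs, and a
  prevalence/VAF-band germline heuristic.

No call is ever dropped silently: every consensus call keeps its full set of
fail-reason codes, and a call passes iff that set is empty.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import (
    Consequence,
    ProteinChange,
    TranscriptModel,
    annotate_consequence,
    flag_hotspot,
    map_domain,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "CallRecord",
    "ConsensusCall",
    "FilterConfig",
    "CohortMatrix",
    "Reason",
    "ReferenceWindow",
    "RunBiasResult",
    "ScreenReport",
    "InvalidAlleleError",
    "DuplicateRecordError",
    "ConfigurationError",
    "normalize_variant",
    "merge_calls",
    "apply_site_filters",
    "detect_recurrent_artifacts",
    "test_run_bias",
    "classify_germline",
    "screen_cohort",
]

_BASES = frozenset("ACGT")


class InvalidAlleleError(ValueError):
    pass


class DuplicateRecordError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class Reason:
    """Fail-reason codes attached to consensus calls by the filter cascade."""

    ONE_CALLER = "ONE_CALLER"
    LOW_COVERAGE = "LOW_COVERAGE"
    LOW_ALT_READS = "LOW_ALT_READS"
    RECURRENT_ARTIFACT = "RECURRENT_ARTIFACT"
    RUN_BIAS = "RUN_BIAS"
    SYNONYMOUS = "SYNONYMOUS"
    NON_CODING = "NON_CODING"
    UNEVALUATED = "UNEVALUATED"
    KNOWN_SNP = "KNOWN_SNP"
    LIKELY_GERMLINE = "LIKELY_GERMLINE"
    OFF_TARGET = "OFF_TARGET"

    ALL = (
        ONE_CALLER,
        LOW_COVERAGE,
        LOW_ALT_READS,
        RECURRENT_ARTIFACT,
        RUN_BIAS,
        SYNONYMOUS,
        NON_CODING,
        UNEVALUATED,
        KNOWN_SNP,
        LIKELY_GERMLINE,
        OFF_TARGET,
    )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized biallelic genomic change (1-based position, VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class CallRecord:
    """One caller's report of one variant in one sample."""

    sample: str
    caller: str
    key: VariantKey
    depth: int
    alt_depth: int
    run: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]"
            )


@dataclass(frozen=True)
class ConsensusCall:
    """Per-(sample, variant) merged evidence with accumulated reason codes."""

    sample: str
    key: VariantKey
    caller_count: int
    depth: int
    alt_depth: int
    reasons: frozenset[str] = frozenset()

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0

    @property
    def status(self) -> str:
        return "PASS" if not self.reasons else "FAIL"

    def with_reasons(self, *codes: str) -> "ConsensusCall":
        if not codes:
            return self
        return replace(self, reasons=self.reasons | frozenset(codes))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    Defaults implement the screen as run: consensus of >=2 callers, >=100
    reads coverage, >=20 alt reads (exclusions are strict inequalities, so
    equality passes), recurrent artifacts at n>=10 samples below 2% VAF,
    run-bias at exact-test alpha 0.001, and restriction to non-synonymous
    coding changes.
    """

    min_callers: int = 2
    min_depth: int = 100
    min_alt_reads: int = 20
    artifact_min_samples: int = 10
    artifact_max_vaf: float = 0.02
    run_bias_alpha: float = 0.001
    require_nonsynonymous: bool = True
    # Germline heuristic (no matched normals): flag a variant carried by more
    # than `germline_max_prevalence` of the cohort with per-sample VAF in the
    # heterozygous or homozygous band.  Off-switchable.
    germline_enabled: bool = True
    germline_max_prevalence: float = 0.10
    germline_het_band: tuple[float, float] = (0.40, 0.60)
    germline_hom_band: tuple[float, float] = (0.90, 1.00)
    run_bias_max_exact_carriers: int = 50
    run_bias_n_resamples: int = 10_000

    def __post_init__(self) -> None:
        if min(self.min_callers, self.min_depth, self.min_alt_reads,
               self.artifact_min_samples) < 1:
            raise ConfigurationError("all count thresholds must be positive")
        if not 0.0 < self.artifact_max_vaf < 1.0:
            raise ConfigurationError("artifact_max_vaf must be in (0, 1)")
        if not 0.0 < self.run_bias_alpha < 1.0:
            raise ConfigurationError("run_bias_alpha must be in (0, 1)")


@dataclass
class CohortMatrix:
    """Variant × sample occurrence map over the full (pre-filter) cohort."""

    entries: dict[VariantKey, list[tuple[str, float, str]]]
    cohort_samples: dict[str, str]  # sample -> run label

    @classmethod
    def from_calls(
        cls,
        calls_by_sample: Mapping[str, Sequence[ConsensusCall]],
        runs: Mapping[str, str],
    ) -> "CohortMatrix":
        entries: dict[VariantKey, list[tuple[str, float, str]]] = {}
        for sample, calls in calls_by_sample.items():
            if sample not in runs:
                raise ConfigurationError(f"sample {sample!r} missing from manifest")
            for call in calls:
                entries.setdefault(call.key, []).append(
                    (sample, call.vaf, runs[sample])
                )
        return cls(entries=entries, cohort_samples=dict(runs))

    @property
    def n_samples(self) -> int:
        return len(self.cohort_samples)

    def runs(self) -> list[str]:
        return sorted(set(self.cohort_samples.values()))


@dataclass(frozen=True)
class RunBiasResult:
    p_value: Optional[float]
    biased: bool
    method: str  # fisher | exact_rx2 | chi2_sim | skipped


class ReferenceWindow:
    """A slice of reference sequence anchored at a 1-based genomic position."""

    def __init__(self, chrom: str, start: int, sequence: str):
        self.chrom = chrom
        self.start = int(start)  # 1-based position of sequence[0]
        self.sequence = sequence.upper()

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def base_at(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise IndexError(f"position {pos} outside window [{self.start}, {self.end}]")
        return self.sequence[pos - self.start]


def normalize_variant(key: VariantKey, reference: Optional[ReferenceWindow] = None) -> VariantKey:
    """Reduce a biallelic variant to its minimal, left-aligned representation.

    Shared leading/trailing bases are trimmed with the position adjusted;
    indels are shifted left through repeat tracts while flanking reference
    bases (from ``reference``, when given) keep the alleles equivalent.
    """
    ref = key.ref.upper()
    alt = key.alt.upper()
    if not ref or not alt or not (set(ref) <= _BASES and set(alt) <= _BASES):
        raise InvalidAlleleError(f"alleles must be non-empty ACGT strings: {key.ref!r}>{key.alt!r}")
    if ref == alt:
        raise InvalidAlleleError(f"ref equals alt at {key.chrom}:{key.pos}")
    if key.pos < 1:
        raise InvalidAlleleError(f"position must be >= 1, got {key.pos}")

    pos = key.pos
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            trimmed = ref[-1]
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                # an allele emptied: extend left with the reference base
                # preceding pos, or restore the trimmed base if we cannot
                if reference is None or pos - 1 < reference.start:
                    ref, alt = ref + trimmed, alt + trimmed
                    break
                base = reference.base_at(pos - 1)
                ref, alt = base + ref, base + alt
                pos -= 1
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            break
    return VariantKey(key.chrom, pos, ref, alt)


def _median_half_up(values: Sequence[int]) -> int:
    """Median with .5 halves rounded up (deterministic tie-break)."""
    m = float(np.median(np.asarray(values, dtype=float)))
    return int(math.floor(m + 0.5))


def merge_calls(records: Sequence[CallRecord]) -> list[ConsensusCall]:
    """Merge one sample's per-caller records into per-variant consensus calls.

    Caller count is the number of distinct callers reporting the key; the
    consensus depth and alt depth are medians across reporting callers
    (halves rounded up) and the VAF is recomputed from the consensus counts.
    """
    if not records:
        return []
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValueError(f"records span multiple samples: {sorted(samples)}")
    seen: set[tuple[str, VariantKey]] = set()
    grouped: dict[VariantKey, list[CallRecord]] = {}
    for rec in records:
        pair = (rec.caller, rec.key)
        if pair in seen:
            raise DuplicateRecordError(f"duplicate record for caller={rec.caller} key={rec.key}")
        seen.add(pair)
        grouped.setdefault(rec.key, []).append(rec)
    out = []
    for key in sorted(grouped):
        group = grouped[key]
        out.append(
            ConsensusCall(
                sample=group[0].sample,
                key=key,
                caller_count=len({r.caller for r in group}),
                depth=_median_half_up([r.depth for r in group]),
                alt_depth=_median_half_up([r.alt_depth for r in group]),
            )
        )
    return out


def apply_site_filters(call: ConsensusCall, cfg: FilterConfig) -> ConsensusCall:
    """Append site-level reason codes (caller agreement, coverage, alt reads).

    Exclusion thresholds are strict: a call at exactly ``min_depth`` reads or
    exactly ``min_alt_reads`` alt reads passes.  Idempotent.
    """
    codes = []
    if call.caller_count < cfg.min_callers:
        codes.append(Reason.ONE_CALLER)
    if call.depth < cfg.min_depth:
        codes.append(Reason.LOW_COVERAGE)
    if call.alt_depth < cfg.min_alt_reads:
        codes.append(Reason.LOW_ALT_READS)
    return call.with_reasons(*codes)


def detect_recurrent_artifacts(
    matrix: CohortMatrix, cfg: FilterConfig
) -> dict[VariantKey, set[str]]:
    """Identify recurrent low-VAF amplification/sequencing artifacts.

    For each variant, the samples carrying it below ``artifact_max_vaf`` are
    flagged when there are at least ``artifact_min_samples`` of them.
    Occurrences at or above the VAF cutoff are never flagged by this rule: a
    genuine somatic event co-located with an amplification artifact is kept.
    """
    flagged: dict[VariantKey, set[str]] = {}
    for key, occ in matrix.entries.items():
        low = {sample for sample, vaf, _ in occ if vaf < cfg.artifact_max_vaf}
        if len(low) >= cfg.artifact_min_samples:
            flagged[key] = low
    return flagged


def _rx2_exact_p(carriers_by_run: np.ndarray, run_sizes: np.ndarray) -> float:
    """Exact two-sided p for an R×2 run × carrier table.

    Enumerates all ways of distributing the carrier total over the runs
    (multivariate hypergeometric) and sums the probability of every table no
    more likely than the observed one.
    """
    K = int(carriers_by_run.sum())
    sizes = [int(n) for n in run_sizes]
    N = sum(sizes)
    log_denom = math.lgamma(N + 1) - math.lgamma(K + 1) - math.lgamma(N - K + 1)

    def log_prob(counts: Sequence[int]) -> float:
        lp = -log_denom
        for k, n in zip(counts, sizes):
            lp += math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        return lp

    lp_obs = log_prob([int(k) for k in carriers_by_run])
    total = 0.0
    ranges = [range(0, min(K, n) + 1) for n in sizes[:-1]]
    for head in itertools.product(*ranges):
        tail = K - sum(head)
        if tail < 0 or tail > sizes[-1]:
            continue
        lp = log_prob(list(head) + [tail])
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def test_run_bias(
    key: VariantKey,
    matrix: CohortMatrix,
    cfg: FilterConfig,
    seed: int = 0,
) -> RunBiasResult:
    """Exact test for unequal distribution of a variant's carriers over runs.

    Builds the R×2 (run × carrier/non-carrier) table.  Two runs: Fisher's
    exact test.  More runs: exact enumeration while the carrier total is at
    most ``run_bias_max_exact_carriers``, otherwise a chi-square statistic
    with a seeded permutation p-value.  Two-sided throughout; a single-run
    cohort skips the test with a warning.
    """
    runs = matrix.runs()
    if len(runs) < 2:
        logger.warning("run-bias test skipped: single sequencing run")
        return RunBiasResult(p_value=None, biased=False, method="skipped")
    run_sizes = np.array(
        [sum(1 for r in matrix.cohort_samples.values() if r == run) for run in runs]
    )
    carrier_samples = {sample for sample, _, _ in matrix.entries.get(key, [])}
    carrier_runs = [matrix.cohort_samples[s] for s in carrier_samples]
    carriers = np.array([sum(1 for r in carrier_runs if r == run) for run in runs])
    K = int(carriers.sum())
    if K == 0:
        return RunBiasResult(p_value=1.0, biased=False, method="exact_rx2")

    if len(runs) == 2:
        table = np.array([carriers, run_sizes - carriers]).T
        _, p = stats.fisher_exact(table, alternative="two-sided")
        method = "fisher"
    elif K <= cfg.run_bias_max_exact_carriers:
        p = _rx2_exact_p(carriers, run_sizes)
        method = "exact_rx2"
    else:
        obs = _chi2_stat(carriers, run_sizes)
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(runs)), run_sizes)
        hits = 0
        for _ in range(cfg.run_bias_n_resamples):
            pick = rng.choice(labels, size=K, replace=False)
            sim = np.bincount(pick, minlength=len(runs))
            if _chi2_stat(sim, run_sizes) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (cfg.run_bias_n_resamples + 1)
        method = "chi2_sim"
    return RunBiasResult(p_value=float(min(p, 1.0)), biased=bool(p < cfg.run_bias_alpha), method=method)


def _chi2_stat(carriers: np.ndarray, run_sizes: np.ndarray) -> float:
    table = np.array([carriers, run_sizes - carriers], dtype=float)
    expected = table.sum(axis=1, keepdims=True) @ table.sum(axis=0, keepdims=True) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(cells.sum())


def classify_germline(
    call: ConsensusCall,
    key: VariantKey,
    snp_list: set[VariantKey],
    matrix: Optional[CohortMatrix] = None,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[str, ...]:
    """Reason codes for known-SNP membership and likely germline origin.

    The germline heuristic (there are no matched normals) flags a variant
    carried by more than ``germline_max_prevalence`` of the cohort with
    per-sample VAF inside the heterozygous [0.40, 0.60] or homozygous
    [0.90, 1.0] band.  Neither flag alone decides pathogenicity.
    """
    codes: list[str] = []
    if key in snp_list:
        codes.append(Reason.KNOWN_SNP)
    if cfg.germline_enabled and matrix is not None and matrix.n_samples:
        lo1, hi1 = cfg.germline_het_band
        lo2, hi2 = cfg.germline_hom_band
        banded = {
            sample
            for sample, vaf, _ in matrix.entries.get(key, [])
            if lo1 <= vaf <= hi1 or lo2 <= vaf <= hi2
        }
        if len(banded) > cfg.germline_max_prevalence * matrix.n_samples:
            codes.append(Reason.LIKELY_GERMLINE)
    return tuple(codes)


# ---------------------------------------------------------------------------
# Cohort orchestration


def _in_targets(key: VariantKey, targets: Mapping[str, Sequence[tuple[int, int]]]) -> bool:
    """BED containment: 0-based half-open intervals vs 1-based variant pos."""
    for start0, end0 in targets.get(key.chrom, ()):
        if start0 <= key.pos - 1 < end0:
            return True
    return False


@dataclass
class ScreenReport:
    """Full audit of a cohort screen: every call with its reasons, plus
    per-stratum summaries (survivor count, cohort size, frequency)."""

    calls: pd.DataFrame
    summary: pd.DataFrame
    config: FilterConfig
    seed: int

    @property
    def survivors(self) -> pd.DataFrame:
        return self.calls[self.calls["status"] == "PASS"]


def screen_cohort(
    records: Iterable[CallRecord],
    manifest: pd.DataFrame,
    models: Sequence[TranscriptModel],
    snp_list: set[VariantKey],
    domains: pd.DataFrame,
    hotspots: pd.DataFrame,
    cfg: FilterConfig = FilterConfig(),
    targets: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
    seed: int = 0,
) -> ScreenReport:
    """Run the full screen: merge → site filters → cohort filters →
    consequence → germline/SNP → domain/hotspot annotation → summary.

    ``manifest`` needs columns sample, cohort, run.  Cohort-level rules
    (artifacts, run bias, germline prevalence) are computed over the entire
    cohort; summaries are reported per ``cohort`` stratum.
    """
    manifest = manifest.copy()
    for col in ("sample", "cohort", "run"):
        if col not in manifest.columns:
            raise ConfigurationError(f"manifest lacks required column {col!r}")
    if manifest["sample"].duplicated().any():
        raise ConfigurationError("duplicate sample ids in manifest")
    runs = dict(zip(manifest["sample"].astype(str), manifest["run"].astype(str)))
    cohorts = dict(zip(manifest["sample"].astype(str), manifest["cohort"].astype(str)))

    by_sample: dict[str, list[CallRecord]] = {}
    for rec in records:
        if rec.sample not in runs:
            raise ConfigurationError(f"call for sample {rec.sample!r} not in manifest")
        by_sample.setdefault(rec.sample, []).append(rec)

    merged: dict[str, list[ConsensusCall]] = {
        sample: merge_calls(recs) for sample, recs in by_sample.items()
    }

    # cohort matrix over pre-filter consensus calls
    matrix = CohortMatrix.from_calls(merged, runs)
    artifacts = detect_recurrent_artifacts(matrix, cfg)
    multi_run = len(matrix.runs()) >= 2
    bias: dict[VariantKey, RunBiasResult] = {}
    if multi_run:
        for key in matrix.entries:
            bias[key] = test_run_bias(key, matrix, cfg, seed=seed)

    model_by_key: dict[VariantKey, Optional[TranscriptModel]] = {}

    def _model_for(key: VariantKey) -> Optional[TranscriptModel]:
        if key not in model_by_key:
            hit = None
            for m in models:
                lo, hi = m.span
                if m.chrom == key.chrom and lo <= key.pos <= hi:
                    hit = m
                    break
            model_by_key[key] = hit
        return model_by_key[key]

    def _row(sample, call, gene="", change=None, domain="", hotspot=False):
        key = call.key
        return {
            "sample": sample,
            "cohort": cohorts[sample],
            "run": runs[sample],
            "chrom": key.chrom,
            "pos": key.pos,
            "ref": key.ref,
            "alt": key.alt,
            "caller_count": call.caller_count,
            "depth": call.depth,
            "alt_depth": call.alt_depth,
            "vaf": call.vaf,
            "gene": gene,
            "protein_change": str(change) if change else "",
            "domain": domain,
            "hotspot": hotspot,
            "reasons": ",".join(sorted(call.reasons)),
            "status": call.status,
        }

    rows = []
    for sample in sorted(merged):
        for call in merged[sample]:
            key = call.key
            if targets is not None and not _in_targets(key, targets):
                # outside the amplicon footprint: out of the screen's scope,
                # dropped immediately without further evaluation
                rows.append(_row(sample, call.with_reasons(Reason.OFF_TARGET)))
                continue
            call = apply_site_filters(call, cfg)
            if key in artifacts and sample in artifacts[key]:
                call = call.with_reasons(Reason.RECURRENT_ARTIFACT)
            if multi_run and bias[key].biased:
                call = call.with_reasons(Reason.RUN_BIAS)

            model = _model_for(key)
            gene = model.gene if model else ""
            change = None
            domain = ""
            hotspot = False
            if model is None:
                consequence = Consequence.NON_CODING
            else:
                consequence = annotate_consequence(key, model)
            if isinstance(consequence, ProteinChange):
                change = consequence
                domain = map_domain(gene, change.codon_index, domains)
                hotspot = flag_hotspot(change, hotspots)
                if cfg.require_nonsynonymous and change.synonymous:
                    call = call.with_reasons(Reason.SYNONYMOUS)
            elif cfg.require_nonsynonymous:
                call = call.with_reasons(
                    Reason.NON_CODING
                    if consequence is Consequence.NON_CODING
                    else Reason.UNEVALUATED
                )
            call = call.with_reasons(
                *classify_germline(call, key, snp_list, matrix, cfg)
            )
            rows.append(_row(sample, call, gene, change, domain, hotspot))

    columns = [
        "sample", "cohort", "run", "chrom", "pos", "ref", "alt", "caller_count",
        "depth", "alt_depth", "vaf", "gene", "protein_change", "domain",
        "hotspot", "reasons", "status",
    ]
    calls_df = pd.DataFrame(rows, columns=columns)

    summary_rows = []
    for cohort, group in manifest.groupby("cohort"):
        n = len(group)
        if calls_df.empty:
            survivors = 0
        else:
            survivors = int(
                ((calls_df["cohort"] == cohort) & (calls_df["status"] == "PASS")).sum()
            )
        summary_rows.append(
            {
                "cohort": cohort,
                "n_samples": n,
                "surviving_variants": survivors,
                "frequency": survivors / n if n else float("nan"),
            }
        )
    summary = pd.DataFrame(summary_rows, columns=["cohort", "n_samples", "surviving_variants", "frequency"])
    return ScreenReport(calls=calls_df, summary=summary, config=cfg, seed=seed)
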