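"""Genotype code-book computations and Ct-based reactivity calling.

A diploid sample's aggregate reactivity pattern is the union of its two
alleles' per-reaction patterns; decoding inverts that union against the
enumerated genotype space, tolerating invalid reactions and a bounded number
of mismatches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .panel_model import ReactivityMatrix

__all__ = [
    "Pattern",
    "CtRecord",
    "ReactivityCall",
    "GenotypeCall",
    "ValidationResult",
    "CutoffCalibration",
    "UniquenessAudit",
    "CT_MAX",
    "DEFAULT_CUTOFF",
    "DEFAULT_INTERNAL_FAIL_CT",
    "DEFAULT_MAX_MISMATCH",
    "allele_pattern",
    "genotype_pattern",
    "enumerate_genotypes",
    "uniqueness_audit",
    "call_reactivity",
    "calibrate_cutoffs",
    "decode",
    "decode_plate",
    "carrier_confusion",
    "is_carrier",
]

#: Ct value encoding "never crossed the threshold".
CT_MAX = 60.0
#: Default per-reaction delta-Ct positivity cutoff (cycles).
DEFAULT_CUTOFF = 7.0
#: Internal-standard Ct at/above which the reaction is invalid.
DEFAULT_INTERNAL_FAIL_CT = 40.0
DEFAULT_MAX_MISMATCH = 1

Genotype = tuple[str, str]  # sorted unordered pair; homozygote = (a, a)


@dataclass(frozen=True)
class Pattern:
    """Set of positively reacting reactions at one locus."""

    locus: str
    reactions: frozenset[str]

    def __or__(self, other: "Pattern") -> "Pattern":
        if self.locus != other.locus:
            raise ValueError("cannot combine patterns from different loci")
        return Pattern(self.locus, self.reactions | other.reactions)

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    reaction_id: str
    ct_specific: float
    ct_internal: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_specific", self.ct_specific), ("ct_internal", self.ct_internal)):
            if not 0.0 <= ct <= CT_MAX:
                raise ValueError(
                    f"{self.sample_id}/{self.reaction_id}: {name}={ct} outside [0, {CT_MAX}]"
                )


@dataclass(frozen=True)
class ReactivityCall:
    sample_id: str
    reaction_id: str
    delta_ct: float
    status: str  # "positive" | "negative" | "invalid"


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    locus: str
    candidates: frozenset[Genotype]
    status: str  # "exact" | "ambiguous_collision" | "nearest_match" | "no_call"
    mismatch_count: int
    invalid_reactions: frozenset[str]
    flags: frozenset[str]

    def candidate_list(self) -> list[Genotype]:
        return sorted(self.candidates)


@dataclass(frozen=True)
class ValidationResult:
    """Carrier-level 2x2 confusion and the four diagnostic proportions.

    Ratios with a zero denominator are ``None`` (absent), never 0.
    """

    allele: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _normalize_genotype(a: str, b: str) -> Genotype:
    return (a, b) if a <= b else (b, a)


def allele_pattern(matrix: ReactivityMatrix, allele: str) -> Pattern:
    """Reactions positive for one allele (one row of the code book)."""
    row = matrix.row(allele)  # KeyError on unknown allele
    return Pattern(matrix.locus, frozenset(r for r, v in zip(matrix.reactions, row) if v))


def genotype_pattern(matrix: ReactivityMatrix, allele1: str, allele2: str) -> Pattern:
    """Aggregate (union) pattern of an unordered allele pair; symmetric."""
    return allele_pattern(matrix, allele1) | allele_pattern(matrix, allele2)


def enumerate_genotypes(matrix: ReactivityMatrix) -> dict[Genotype, Pattern]:
    """All n(n+1)/2 unordered genotypes (incl. homozygotes) with their patterns."""
    single = {a: allele_pattern(matrix, a) for a in matrix.alleles}
    return {
        _normalize_genotype(a, b): single[a] | single[b]
        for a, b in itertools.combinations_with_replacement(sorted(matrix.alleles), 2)
    }


@dataclass
class UniquenessAudit:
    locus: str
    total_genotypes: int
    distinct_pattern_count: int
    collision_groups: list[list[Genotype]]

    @property
    def unique_genotype_count(self) -> int:
        return self.total_genotypes - sum(len(g) for g in self.collision_groups)


def uniqueness_audit(matrix: ReactivityMatrix) -> UniquenessAudit:
    """Count distinct genotype patterns and list every collision group."""
    genotypes = enumerate_genotypes(matrix)
    by_pattern: dict[frozenset[str], list[Genotype]] = {}
    for g, p in genotypes.items():
        by_pattern.setdefault(p.reactions, []).append(g)
    groups = sorted(sorted(v) for v in by_pattern.values() if len(v) > 1)
    return UniquenessAudit(
        locus=matrix.locus,
        total_genotypes=len(genotypes),
        distinct_pattern_count=len(by_pattern),
        collision_groups=groups,
    )


# ---------------------------------------------------------------------------
# Reactivity calling
# ---------------------------------------------------------------------------


def call_reactivity(
    records: Iterable[CtRecord],
    cutoffs: float | Mapping[str, float] = DEFAULT_CUTOFF,
    internal_fail_ct: float = DEFAULT_INTERNAL_FAIL_CT,
    known_reactions: Iterable[str] | None = None,
) -> list[ReactivityCall]:
    """Interpret paired Ct measurements as positive/negative/invalid calls.

    ``cutoffs`` may be a single global delta-Ct threshold or a per-reaction
    mapping.  A record whose internal-standard Ct is at or above
    ``internal_fail_ct`` is invalid regardless of the specific signal.
    """
    known = set(known_reactions) if known_reactions is not None else None
    if isinstance(cutoffs, Mapping):
        get_cutoff = lambda r: cutoffs.get(r, DEFAULT_CUTOFF)  # noqa: E731
    else:
        get_cutoff = lambda r: float(cutoffs)  # noqa: E731
    calls = []
    for rec in records:
        if known is not None and rec.reaction_id not in known:
            raise KeyError(f"unknown reaction id {rec.reaction_id!r}")
        delta = rec.ct_specific - rec.ct_internal
        if rec.ct_internal >= internal_fail_ct:
            status = "invalid"
        elif delta <= get_cutoff(rec.reaction_id):
            status = "positive"
        else:
            status = "negative"
        calls.append(ReactivityCall(rec.sample_id, rec.reaction_id, delta, status))
    return calls


@dataclass(frozen=True)
class CutoffCalibration:
    reaction_id: str
    cutoff: float
    flags: frozenset[str]  # subset of {"non_separable", "fallback"}


def calibrate_cutoffs(
    records: Iterable[CtRecord],
    known_reactivities: Mapping[tuple[str, str], bool],
    default_cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, CutoffCalibration]:
    """Midpoint cutoffs from labeled training records.

    The cutoff for a reaction is the midpoint between the largest delta-Ct
    among known positives and the smallest among known negatives.  Reactions
    where the classes overlap are flagged ``non_separable``; reactions missing
    one class fall back to ``default_cutoff`` with a ``fallback`` flag.
    """
    pos: dict[str, list[float]] = {}
    neg: dict[str, list[float]] = {}
    for rec in records:
        key = (rec.sample_id, rec.reaction_id)
        if key not in known_reactivities:
            continue
        delta = rec.ct_specific - rec.ct_internal
        (pos if known_reactivities[key] else neg).setdefault(rec.reaction_id, []).append(delta)
    out: dict[str, CutoffCalibration] = {}
    for rid in sorted(set(pos) | set(neg)):
        if rid not in pos or rid not in neg:
            out[rid] = CutoffCalibration(rid, default_cutoff, frozenset({"fallback"}))
            continue
        hi_pos, lo_neg = max(pos[rid]), min(neg[rid])
        cutoff = (hi_pos + lo_neg) / 2.0
        flags = frozenset({"non_separable"}) if hi_pos >= lo_neg else frozenset()
        out[rid] = CutoffCalibration(rid, cutoff, flags)
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def decode(
    observed: Pattern | frozenset[str] | set[str],
    valid_reactions: Iterable[str],
    matrix: ReactivityMatrix,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    sample_id: str = "",
) -> GenotypeCall:
    """Invert an observed aggregate pattern to candidate genotypes.

    Only reactions in ``valid_reactions`` are compared.  Exact matches (on the
    valid restriction) win; otherwise genotypes minimizing the symmetric
    difference are returned when that minimum is within ``max_mismatch``.
    Uninterpretable input yields a ``no_call``, never an exception.
    """
    obs = observed.reactions if isinstance(observed, Pattern) else frozenset(observed)
    valid = frozenset(valid_reactions)
    if not obs <= valid:
        raise ValueError("observed pattern contains reactions outside valid_reactions")
    invalid = frozenset(matrix.reactions) - valid
    locus = matrix.locus

    if not obs:
        return GenotypeCall(sample_id, locus, frozenset(), "no_call", 0, invalid,
                            frozenset({"all_negative"}))

    genotypes = enumerate_genotypes(matrix)
    exact: list[Genotype] = []
    best: list[Genotype] = []
    best_d = None
    for g, p in genotypes.items():
        d = len((p.reactions & valid) ^ obs)
        if d == 0:
            exact.append(g)
        if best_d is None or d < best_d:
            best, best_d = [g], d
        elif d == best_d:
            best.append(g)

    def flags_for(cands: Sequence[Genotype], extra: frozenset[str] = frozenset()) -> frozenset[str]:
        f = set(extra)
        if any(a == b for a, b in cands):
            f.add("homozygote_overcall_risk")
        return frozenset(f)

    if exact:
        status = "exact" if len(exact) == 1 else "ambiguous_collision"
        return GenotypeCall(sample_id, locus, frozenset(exact), status, 0, invalid,
                            flags_for(exact))
    if best_d is not None and best_d <= max_mismatch:
        return GenotypeCall(sample_id, locus, frozenset(best), "nearest_match",
                            best_d, invalid,
                            flags_for(best, frozenset({"possible_nonaddressed"})))
    return GenotypeCall(sample_id, locus, frozenset(), "no_call",
                        best_d if best_d is not None else 0, invalid, frozenset())


def decode_plate(
    calls: Iterable[ReactivityCall],
    matrix: ReactivityMatrix,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> dict[str, GenotypeCall]:
    """Group per-reaction calls by sample and decode each sample's pattern."""
    all_reactions = frozenset(matrix.reactions)
    by_sample: dict[str, dict[str, str]] = {}
    for c in calls:
        if c.reaction_id not in all_reactions:
            raise KeyError(f"unknown reaction id {c.reaction_id!r}")
        by_sample.setdefault(c.sample_id, {})[c.reaction_id] = c.status
    out: dict[str, GenotypeCall] = {}
    for sample_id in sorted(by_sample):
        statuses = by_sample[sample_id]
        valid = frozenset(r for r in matrix.reactions
                          if statuses.get(r, "invalid") != "invalid")
        obs = frozenset(r for r, s in statuses.items() if s == "positive")
        out[sample_id] = decode(obs, valid, matrix, max_mismatch, sample_id)
    return out


# ---------------------------------------------------------------------------
# Carrier-level validation
# ---------------------------------------------------------------------------


def is_carrier(call: GenotypeCall, allele: str) -> bool:
    """Conservative carrier assignment: every candidate must contain the allele."""
    if not call.candidates:
        return False
    return all(allele in g for g in call.candidates)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def carrier_confusion(
    calls: Mapping[str, GenotypeCall],
    truth: Mapping[str, Genotype],
    allele: str,
) -> ValidationResult:
    """Carrier-level 2x2 table of called vs true carriage for one allele."""
    missing = sorted(s for s in truth if s not in calls)
    if missing:
        raise KeyError(f"samples in truth but not in calls: {', '.join(missing)}")
    tp = fp = tn = fn = 0
    for sample_id, genotype in truth.items():
        truly = allele in genotype
        called = is_carrier(calls[sample_id], allele)
        if truly and called:
            tp += 1
        elif truly:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ValidationResult(
        allele=allele, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )
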