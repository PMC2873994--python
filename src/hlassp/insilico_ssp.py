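"""In-silico SSP reactivity prediction from allele template sequences.

Encodes the panel's design rules as a binary matcher: primer 3'-end bases must
match perfectly, LNA bases must match exactly wherever they fall, IUPAC
degeneracy applies elsewhere with a bounded mismatch allowance, amplicons must
stay under a length bound, and the probe must sit inside the amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .panel_model import Panel, Primer, Probe, Reaction, ReactivityMatrix

__all__ = [
    "IUPAC",
    "MatchRules",
    "AlleleSequence",
    "PrimerSite",
    "PredictedReactivity",
    "iupac_compatible",
    "reverse_complement",
    "find_primer_sites",
    "predict_amplicons",
    "probe_sites",
    "predict_reaction",
    "predict_matrix",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_compatible(primer_base: str, template_base: str) -> bool:
    """True iff the template base lies in the primer base's degeneracy expansion."""
    try:
        expansion = IUPAC[primer_base]
    except KeyError:
        raise ValueError(f"invalid IUPAC symbol {primer_base!r}") from None
    if template_base not in "ACGT":
        raise ValueError(f"invalid template base {template_base!r}")
    return template_base in expansion


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchRules:
    """Binary amplification model parameters."""

    three_prime_exact: int = 3  # 3'-terminal bases that must match with no mismatch
    max_other_mismatch: int = 0  # IUPAC-incompatible positions tolerated elsewhere
    max_amplicon: int = 250  # amplicons at/above this length do not amplify


@dataclass(frozen=True)
class AlleleSequence:
    """Named template covering the first-round amplicon region (1-based coords)."""

    name: str
    template: str

    def __post_init__(self) -> None:
        if not set(self.template) <= set("ACGT"):
            bad = sorted(set(self.template) - set("ACGT"))
            raise ValueError(f"template {self.name}: non-ACGT symbols {bad}")


@dataclass(frozen=True)
class PrimerSite:
    """Primer placement on a template; ``position`` is the 5'-end coordinate."""

    primer: str
    position: int  # 1-based coordinate of the primer's 5' end
    strand: str  # "plus" | "minus"
    start: int  # leftmost template coordinate of the site (1-based inclusive)
    end: int  # rightmost template coordinate

    @property
    def three_prime(self) -> int:
        """Template coordinate under the primer's 3'-terminal base."""
        return self.end if self.strand == "plus" else self.start


def _as_oligo(primer: Primer | Probe | str) -> tuple[str, str, frozenset[int]]:
    if isinstance(primer, (Primer, Probe)):
        lna = primer.lna_positions if isinstance(primer, Primer) else frozenset()
        return primer.name, primer.sequence, lna
    return str(primer), str(primer), frozenset()


def find_primer_sites(
    template: str,
    primer: Primer | str,
    strand: str = "plus",
    three_prime_exact: int = 3,
    max_other_mismatch: int = 0,
) -> list[PrimerSite]:
    """Full-length primer placements satisfying the 3'-exactness and LNA rules.

    On the minus strand the primer is matched against the template's reverse
    complement, so its 3' end faces leftward in template coordinates.
    """
    if three_prime_exact < 1:
        raise ValueError("three_prime_exact must be >= 1")
    if max_other_mismatch < 0:
        raise ValueError("max_other_mismatch must be >= 0")
    if strand not in ("plus", "minus"):
        raise ValueError(f"unknown strand {strand!r}")
    name, seq, lna = _as_oligo(primer)
    n, L = len(template), len(seq)
    if L > n:
        return []
    if strand == "minus":
        # match in reverse-complement space; primer position i sits at
        # template coordinate (offset + L - i) 1-based
        probe_seq = reverse_complement(seq)
        lna = frozenset(L - 1 - i for i in lna)
        strict = frozenset(range(three_prime_exact))  # 3' end is leftmost after rc
    else:
        probe_seq = seq
        strict = frozenset(range(L - three_prime_exact, L))
    sites = []
    for off in range(n - L + 1):
        mismatches = 0
        ok = True
        for i, pb in enumerate(probe_seq):
            compatible = template[off + i] in IUPAC[pb]
            exact = template[off + i] == pb
            if i in lna and not exact:
                ok = False
                break
            if not compatible:
                if i in strict:
                    ok = False
                    break
                mismatches += 1
                if mismatches > max_other_mismatch:
                    ok = False
                    break
        if ok:
            start, end = off + 1, off + L
            position = start if strand == "plus" else end
            sites.append(PrimerSite(name, position, strand, start, end))
    return sites


def predict_amplicons(
    template: str,
    fwd_primer: Primer | str,
    rev_primer: Primer | str,
    max_len: int = 250,
    three_prime_exact: int = 3,
    max_other_mismatch: int = 0,
) -> list[tuple[int, int]]:
    """Amplifiable (start, end) spans: fwd 5' to rev 5', shorter than max_len."""
    fwd_sites = find_primer_sites(template, fwd_primer, "plus",
                                  three_prime_exact, max_other_mismatch)
    rev_sites = find_primer_sites(template, rev_primer, "minus",
                                  three_prime_exact, max_other_mismatch)
    spans = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.three_prime <= f.three_prime:
                continue
            start, end = f.position, r.position
            if end - start + 1 < max_len:
                spans.append((start, end))
    return sorted(spans)


def probe_sites(template: str, probe: Probe | str) -> list[tuple[int, int]]:
    """IUPAC-exact probe placements on either strand, as 1-based spans."""
    name, seq, _ = _as_oligo(probe)
    spans = set()
    for variant in (seq, reverse_complement(seq)):
        L = len(variant)
        for off in range(len(template) - L + 1):
            if all(template[off + i] in IUPAC[b] for i, b in enumerate(variant)):
                spans.add((off + 1, off + L))
    return sorted(spans)


@dataclass(frozen=True)
class PredictedReactivity:
    specific_reactive: bool
    internal_valid: bool


def _pair_reactive(
    template: str,
    fwd: Primer,
    rev: Primer,
    probe: Probe,
    rules: MatchRules,
) -> bool:
    amplicons = predict_amplicons(
        template, fwd, rev, rules.max_amplicon,
        rules.three_prime_exact, rules.max_other_mismatch,
    )
    if not amplicons:
        return False
    psites = probe_sites(template, probe)
    return any(
        a_start <= p_start and p_end <= a_end
        for a_start, a_end in amplicons
        for p_start, p_end in psites
    )


def predict_reaction(
    allele_seq: AlleleSequence,
    reaction: Reaction,
    panel: Panel,
    rules: MatchRules = MatchRules(),
) -> PredictedReactivity:
    """Predict one reaction: specific primer pair + probe, and internal standard."""
    def primer(name: str) -> Primer:
        if name not in panel.primers:
            raise KeyError(f"primer {name!r} not in panel")
        return panel.primers[name]

    def probe(name: str) -> Probe:
        if name not in panel.probes:
            raise KeyError(f"probe {name!r} not in panel")
        return panel.probes[name]

    t = allele_seq.template
    specific = _pair_reactive(t, primer(reaction.specific_fwd),
                              primer(reaction.specific_rev),
                              probe(reaction.specific_probe), rules)
    internal = _pair_reactive(t, primer(reaction.internal_fwd),
                              primer(reaction.internal_rev),
                              probe(reaction.internal_probe), rules)
    return PredictedReactivity(specific, internal)


@dataclass
class MatrixPrediction:
    matrix: ReactivityMatrix
    internal_valid: dict[str, bool]
    #: (allele, reaction_id, predicted, curated) for every differing cell
    discrepancies: list[tuple[str, str, bool, bool]]


def predict_matrix(
    allele_seqs: Iterable[AlleleSequence] | Mapping[str, str],
    panel: Panel,
    locus: str,
    rules: MatchRules = MatchRules(),
    curated: ReactivityMatrix | None = None,
) -> MatrixPrediction:
    """Predict the full allele x reaction matrix and diff it against a curated one."""
    if isinstance(allele_seqs, Mapping):
        seqs = [AlleleSequence(k, v) for k, v in allele_seqs.items()]
    else:
        seqs = list(allele_seqs)
    reactions = panel.reactions[locus]
    alleles = [s.name for s in seqs]
    cells = np.zeros((len(seqs), len(reactions)), dtype=bool)
    internal_valid = {}
    for i, s in enumerate(seqs):
        ok = True
        for j, rxn in enumerate(reactions):
            pred = predict_reaction(s, rxn, panel, rules)
            cells[i, j] = pred.specific_reactive
            ok = ok and pred.internal_valid
        internal_valid[s.name] = ok
    predicted = ReactivityMatrix(locus, alleles, [r.id for r in reactions], cells)
    discrepancies: list[tuple[str, str, bool, bool]] = []
    if curated is not None:
        for a in alleles:
            for r in predicted.reactions:
                want = curated.cell(a, r) if a in curated.alleles else False
                got = predicted.cell(a, r)
                if want != got:
                    discrepancies.append((a, r, got, want))
    return MatrixPrediction(predicted, internal_valid, discrepancies)
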