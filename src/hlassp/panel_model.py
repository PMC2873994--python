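"""Typing-panel data model: primers, probes, reactions and reactivity matrices.

The panel is distributed as one structured-text file per locus (sections
``[primers]``, ``[probes]``, ``[reactions]``) plus transcribed reactivity
matrices for HLA-A and HLA-C.  Primer sequences keep the bracketed
locked-nucleic-acid (LNA) notation of the source tables on disk and are parsed
into a plain sequence plus a set of LNA positions at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Primer",
    "Probe",
    "Reaction",
    "Panel",
    "ReactivityMatrix",
    "PanelAudit",
    "PanelError",
    "PanelFormatError",
    "PanelSchemaError",
    "PanelIntegrityError",
    "parse_bracketed",
    "format_bracketed",
    "load_panel",
    "load_default_panel",
    "load_matrix",
    "load_default_matrix",
    "serialize_locus",
    "reactivity_matrix",
    "audit_panel",
]

LOCI = ("HLA-A", "HLA-B", "HLA-C")

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: Reference-coordinate boundary separating the two target exons: all
#: exon-2 oligos end well before it and all exon-3 oligos start well after it,
#: for every locus in the published panel.
EXON_BOUNDARY = 600

#: Published census used by the audit: (primers, probes, reactions, alleles).
EXPECTED_COUNTS = {
    "HLA-A": (31, 3, 20, 14),
    "HLA-B": (50, 2, 46, 23),
    "HLA-C": (26, 2, 15, 12),
}
EXPECTED_TOTAL_PROBES = 7
EXPECTED_TOTAL_ALLELES = 49


class PanelError(Exception):
    """Base class for panel-definition problems."""


class PanelFormatError(PanelError):
    """A panel file line could not be parsed."""


class PanelSchemaError(PanelError):
    """Duplicate identifiers or malformed file structure."""


class PanelIntegrityError(PanelError):
    """Cross-reference or content violations (missing oligos, empty panel)."""


def parse_bracketed(text: str) -> tuple[str, frozenset[int]]:
    """Strip ``[X]`` LNA brackets from an oligo sequence.

    Returns the plain sequence and the 0-based positions of the bracketed
    bases, e.g. ``"AGT[C]" -> ("AGTC", {3})``.
    """
    seq: list[str] = []
    lna: set[int] = set()
    in_bracket = False
    for ch in text:
        if ch == "[":
            if in_bracket:
                raise PanelFormatError(f"nested '[' in sequence {text!r}")
            in_bracket = True
        elif ch == "]":
            if not in_bracket:
                raise PanelFormatError(f"unmatched ']' in sequence {text!r}")
            in_bracket = False
        else:
            if ch not in IUPAC_ALPHABET:
                raise PanelFormatError(f"non-IUPAC symbol {ch!r} in sequence {text!r}")
            if in_bracket:
                lna.add(len(seq))
            seq.append(ch)
    if in_bracket:
        raise PanelFormatError(f"unterminated '[' in sequence {text!r}")
    return "".join(seq), frozenset(lna)


def format_bracketed(sequence: str, lna_positions: Iterable[int]) -> str:
    lna = set(lna_positions)
    return "".join(f"[{b}]" if i in lna else b for i, b in enumerate(sequence))


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    lna_positions: frozenset[int]
    orientation: str  # "forward" | "reverse"
    locus: str
    ref_span: tuple[int, int]  # 1-based inclusive, stored verbatim from source

    def __post_init__(self) -> None:
        if not set(self.sequence) <= IUPAC_ALPHABET:
            raise PanelFormatError(f"primer {self.name}: non-IUPAC sequence")
        if not all(0 <= i < len(self.sequence) for i in self.lna_positions):
            raise PanelIntegrityError(f"primer {self.name}: LNA index out of range")

    @property
    def bracketed(self) -> str:
        return format_bracketed(self.sequence, self.lna_positions)


@dataclass(frozen=True)
class Probe:
    name: str
    dye: str  # "FAM" | "TET"
    quencher: str  # "BHQ1"
    sequence: str
    locus: str
    ref_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PanelIntegrityError(f"probe {self.name}: empty sequence")
        if self.dye not in ("FAM", "TET"):
            raise PanelFormatError(f"probe {self.name}: unknown dye {self.dye!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    locus: str
    specific_fwd: str
    specific_rev: str
    specific_probe: str
    internal_fwd: str
    internal_rev: str
    internal_probe: str
    addressed_alleles: frozenset[str]


@dataclass
class Panel:
    """Ordered reactions, addressed-allele lists and oligo registries per locus."""

    reactions: dict[str, list[Reaction]] = field(default_factory=dict)
    alleles: dict[str, list[str]] = field(default_factory=dict)
    primers: dict[str, Primer] = field(default_factory=dict)
    probes: dict[str, Probe] = field(default_factory=dict)
    reference: dict[str, str] = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        return list(self.reactions)

    def reaction(self, reaction_id: str) -> Reaction:
        for rxns in self.reactions.values():
            for r in rxns:
                if r.id == reaction_id:
                    return r
        raise KeyError(reaction_id)

    def reaction_ids(self, locus: str) -> list[str]:
        return [r.id for r in self.reactions[locus]]

    def locus_primers(self, locus: str) -> list[Primer]:
        return [p for p in self.primers.values() if p.locus == locus]

    def locus_probes(self, locus: str) -> list[Probe]:
        return [p for p in self.probes.values() if p.locus == locus]


@dataclass
class ReactivityMatrix:
    """Boolean allele x reaction matrix (the genotype code book for one locus)."""

    locus: str
    alleles: list[str]
    reactions: list[str]
    cells: np.ndarray  # bool, shape (len(alleles), len(reactions))

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != (len(self.alleles), len(self.reactions)):
            raise ValueError("matrix shape does not match allele/reaction lists")
        self._row = {a: i for i, a in enumerate(self.alleles)}
        self._col = {r: j for j, r in enumerate(self.reactions)}

    def cell(self, allele: str, reaction_id: str) -> bool:
        return bool(self.cells[self._row[allele], self._col[reaction_id]])

    def row(self, allele: str) -> np.ndarray:
        if allele not in self._row:
            raise KeyError(f"allele {allele!r} not in {self.locus} matrix")
        return self.cells[self._row[allele]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactivityMatrix):
            return NotImplemented
        return (
            self.locus == other.locus
            and self.alleles == other.alleles
            and self.reactions == other.reactions
            and bool(np.array_equal(self.cells, other.cells))
        )


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_LOCUS_FILES = {"HLA-A": "hla_a.panel", "HLA-B": "hla_b.panel", "HLA-C": "hla_c.panel"}
_MATRIX_FILES = {"HLA-A": "hla_a.matrix", "HLA-C": "hla_c.matrix"}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hlassp").joinpath("data", name)))


def _parse_span(text: str, where: str) -> tuple[int, int]:
    try:
        a, b = text.split("-")
        return int(a), int(b)
    except ValueError as exc:
        raise PanelFormatError(f"{where}: bad span {text!r}") from exc


def _orientation_from_name(name: str) -> str:
    # primer ids carry F/R before the trailing serial, e.g. A228F04, B911R02
    tag = name[-3]
    if tag == "F":
        return "forward"
    if tag == "R":
        return "reverse"
    raise PanelFormatError(f"primer {name!r}: cannot infer orientation")


def _parse_locus_file(path: Path, panel: Panel) -> None:
    locus = None
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        where = f"{path.name}:{lineno}"
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section not in ("primers", "probes", "reactions"):
                raise PanelFormatError(f"{where}: unknown section {section!r}")
            continue
        fields = line.split("\t")
        if section is None:
            if fields[0] == "locus" and len(fields) == 2:
                locus = fields[1]
                if locus in panel.reactions:
                    raise PanelSchemaError(f"{where}: duplicate locus {locus!r}")
                panel.reactions[locus] = []
                panel.alleles[locus] = []
                continue
            if fields[0] == "reference" and len(fields) == 2 and locus:
                panel.reference[locus] = fields[1]
                continue
            raise PanelFormatError(f"{where}: expected header field, got {line!r}")
        if locus is None:
            raise PanelFormatError(f"{where}: section before 'locus' header")
        if section == "primers":
            if len(fields) != 4:
                raise PanelFormatError(f"{where}: primer row needs 4 fields")
            name, bracketed, orientation, span = fields
            if name in panel.primers:
                raise PanelSchemaError(f"{where}: duplicate primer {name!r}")
            seq, lna = parse_bracketed(bracketed)
            panel.primers[name] = Primer(
                name, seq, lna, orientation, locus, _parse_span(span, where)
            )
        elif section == "probes":
            if len(fields) != 5:
                raise PanelFormatError(f"{where}: probe row needs 5 fields")
            name, dye, quencher, seq, span = fields
            if name in panel.probes:
                raise PanelSchemaError(f"{where}: duplicate probe {name!r}")
            panel.probes[name] = Probe(
                name, dye, quencher, seq, locus, _parse_span(span, where)
            )
        else:  # reactions
            if len(fields) != 8:
                raise PanelFormatError(f"{where}: reaction row needs 8 fields")
            rid, sf, sr, sp, inf, inr, inp, addressed = fields
            if any(r.id == rid for r in panel.reactions[locus]):
                raise PanelSchemaError(f"{where}: duplicate reaction id {rid!r}")
            alleles = frozenset(a for a in addressed.split(",") if a)
            rxn = Reaction(rid, locus, sf, sr, sp, inf, inr, inp, alleles)
            for oligo in (sf, sr, inf, inr):
                if oligo not in panel.primers:
                    raise PanelIntegrityError(f"{where}: unknown primer {oligo!r}")
            for oligo in (sp, inp):
                if oligo not in panel.probes:
                    raise PanelIntegrityError(f"{where}: unknown probe {oligo!r}")
            panel.reactions[locus].append(rxn)
            for a in sorted(alleles):
                if a not in panel.alleles[locus]:
                    panel.alleles[locus].append(a)
    if locus is None:
        raise PanelFormatError(f"{path.name}: missing 'locus' header")
    panel.alleles[locus] = sorted(panel.alleles[locus])
    if not panel.reactions[locus]:
        raise PanelIntegrityError(f"{path.name}: no reactions defined for {locus}")


def load_panel(panel_path: str | Path) -> Panel:
    """Load a panel from a single locus file or a directory of ``*.panel`` files."""
    path = Path(panel_path)
    panel = Panel()
    if path.is_dir():
        files = sorted(path.glob("*.panel"))
        if not files:
            raise PanelIntegrityError(f"{path}: no *.panel files found")
        for f in files:
            _parse_locus_file(f, panel)
    else:
        _parse_locus_file(path, panel)
    return panel


def load_default_panel() -> Panel:
    """Load the packaged three-locus panel."""
    panel = Panel()
    for locus in LOCI:
        _parse_locus_file(_data_path(_LOCUS_FILES[locus]), panel)
    return panel


def serialize_locus(panel: Panel, locus: str) -> str:
    """Canonical text form of one locus; inverse of the file parser."""
    if locus not in panel.reactions:
        raise KeyError(locus)
    out = [f"locus\t{locus}"]
    if locus in panel.reference:
        out.append(f"reference\t{panel.reference[locus]}")
    out.append("")
    out.append("[primers]")
    for p in panel.locus_primers(locus):
        out.append(f"{p.name}\t{p.bracketed}\t{p.orientation}\t{p.ref_span[0]}-{p.ref_span[1]}")
    out.append("")
    out.append("[probes]")
    for p in panel.locus_probes(locus):
        out.append(f"{p.name}\t{p.dye}\t{p.quencher}\t{p.sequence}\t{p.ref_span[0]}-{p.ref_span[1]}")
    out.append("")
    out.append("[reactions]")
    for r in panel.reactions[locus]:
        addressed = ",".join(sorted(r.addressed_alleles))
        out.append(
            f"{r.id}\t{r.specific_fwd}\t{r.specific_rev}\t{r.specific_probe}"
            f"\t{r.internal_fwd}\t{r.internal_rev}\t{r.internal_probe}\t{addressed}"
        )
    return "\n".join(out) + "\n"


def reactivity_matrix(panel: Panel, locus: str) -> ReactivityMatrix:
    """Build the allele x reaction matrix from the reactions' addressed lists."""
    if locus not in panel.reactions:
        raise KeyError(f"locus {locus!r} not in panel")
    alleles = panel.alleles[locus]
    rxns = panel.reactions[locus]
    cells = np.zeros((len(alleles), len(rxns)), dtype=bool)
    for j, r in enumerate(rxns):
        for a in r.addressed_alleles:
            cells[alleles.index(a), j] = True
    return ReactivityMatrix(locus, list(alleles), [r.id for r in rxns], cells)


def load_matrix(path: str | Path) -> ReactivityMatrix:
    """Load a transcribed reactivity-matrix file (reactions as rows, X marks)."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")]
    if not lines or not lines[0].startswith("locus\t"):
        raise PanelFormatError(f"{path}: missing locus header")
    locus = lines[0].split("\t")[1]
    alleles = lines[1].split("\t")[1:]
    reactions: list[str] = []
    rows: list[list[bool]] = []
    for line in lines[2:]:
        fields = line.split("\t")
        if len(fields) != len(alleles) + 1:
            raise PanelFormatError(f"{path}: row {fields[0]!r} has wrong width")
        reactions.append(fields[0])
        rows.append([c == "X" for c in fields[1:]])
    cells = np.array(rows, dtype=bool).T  # file is reaction-major; matrix is allele-major
    return ReactivityMatrix(locus, alleles, reactions, cells)


def load_default_matrix(locus: str) -> ReactivityMatrix:
    """Load the packaged transcription of the published matrix (HLA-A, HLA-C)."""
    if locus not in _MATRIX_FILES:
        raise KeyError(f"no transcribed matrix packaged for {locus!r}")
    return load_matrix(_data_path(_MATRIX_FILES[locus]))


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------


@dataclass
class PanelAudit:
    primer_counts: dict[str, int]
    probe_counts: dict[str, int]
    total_probes: int
    reaction_counts: dict[str, int]
    allele_counts: dict[str, int]
    total_alleles: int
    checks: list[tuple[str, bool, str]]  # (name, passed, detail)
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def failed(self) -> list[tuple[str, bool, str]]:
        return [c for c in self.checks if not c[1]]

    def to_dict(self) -> dict:
        return {
            "primer_counts": self.primer_counts,
            "probe_counts": self.probe_counts,
            "total_probes": self.total_probes,
            "reaction_counts": self.reaction_counts,
            "allele_counts": self.allele_counts,
            "total_alleles": self.total_alleles,
            "ok": self.ok,
            "checks": [
                {"name": n, "passed": p, "detail": d} for n, p, d in self.checks
            ],
            "warnings": list(self.warnings),
        }

    def to_text(self) -> str:
        out = ["Panel audit", "==========="]
        for locus in self.reaction_counts:
            out.append(
                f"{locus}: {self.primer_counts[locus]} primers, "
                f"{self.probe_counts[locus]} probes, "
                f"{self.reaction_counts[locus]} reactions, "
                f"{self.allele_counts[locus]} addressed alleles"
            )
        out.append(f"total probes: {self.total_probes}")
        out.append(f"total addressed alleles: {self.total_alleles}")
        out.append(f"invariants: {'all pass' if self.ok else 'FAILURES'}")
        for name, passed, detail in self.checks:
            out.append(f"  [{'ok' if passed else 'FAIL'}] {name}" + (f": {detail}" if detail else ""))
        for w in self.warnings:
            out.append(f"  [warn] {w}")
        return "\n".join(out) + "\n"


def audit_panel(panel: Panel) -> PanelAudit:
    """Census and invariant report; violations are reported, never raised."""
    checks: list[tuple[str, bool, str]] = []
    warnings: list[str] = []

    def check(name: str, passed: bool, detail: str = "") -> None:
        checks.append((name, bool(passed), detail))

    primer_counts = {l: len(panel.locus_primers(l)) for l in panel.loci}
    probe_counts = {l: len(panel.locus_probes(l)) for l in panel.loci}
    reaction_counts = {l: len(panel.reactions[l]) for l in panel.loci}
    allele_counts = {l: len(panel.alleles[l]) for l in panel.loci}
    total_probes = len(panel.probes)
    total_alleles = sum(allele_counts.values())

    for locus in panel.loci:
        expected = EXPECTED_COUNTS.get(locus)
        if expected is not None:
            n_pr, n_pb, n_rx, n_al = expected
            check(f"{locus} primer count == {n_pr}", primer_counts[locus] == n_pr,
                  f"found {primer_counts[locus]}")
            check(f"{locus} reaction count == {n_rx}", reaction_counts[locus] == n_rx,
                  f"found {reaction_counts[locus]}")
            check(f"{locus} addressed-allele count == {n_al}", allele_counts[locus] == n_al,
                  f"found {allele_counts[locus]}")
    if set(panel.loci) == set(LOCI):
        check(f"total probe count == {EXPECTED_TOTAL_PROBES}",
              total_probes == EXPECTED_TOTAL_PROBES, f"found {total_probes}")
        check(f"total addressed alleles == {EXPECTED_TOTAL_ALLELES}",
              total_alleles == EXPECTED_TOTAL_ALLELES, f"found {total_alleles}")

    for locus in panel.loci:
        pairs: dict[tuple[str, str], str] = {}
        for r in panel.reactions[locus]:
            check(f"{r.id} addressed set non-empty", len(r.addressed_alleles) > 0)
            missing = [o for o in (r.specific_fwd, r.specific_rev, r.internal_fwd,
                                   r.internal_rev) if o not in panel.primers]
            missing += [o for o in (r.specific_probe, r.internal_probe)
                        if o not in panel.probes]
            check(f"{r.id} oligo references resolve", not missing, ",".join(missing))
            if r.specific_probe in panel.probes and r.internal_probe in panel.probes:
                check(
                    f"{r.id} specific/internal probes carry different dyes",
                    panel.probes[r.specific_probe].dye != panel.probes[r.internal_probe].dye,
                )
            sp = [panel.primers[o] for o in (r.specific_fwd, r.specific_rev)
                  if o in panel.primers]
            ip = [panel.primers[o] for o in (r.internal_fwd, r.internal_rev)
                  if o in panel.primers]
            if len(sp) == 2 and len(ip) == 2:
                sp_side = {p.ref_span[0] > EXON_BOUNDARY for p in sp}
                ip_side = {p.ref_span[0] > EXON_BOUNDARY for p in ip}
                check(
                    f"{r.id} specific/internal pairs target converse exons",
                    len(sp_side) == 1 and len(ip_side) == 1 and sp_side != ip_side,
                )
            key = (r.specific_fwd, r.specific_rev)
            if key in pairs:
                check(f"{locus} specific primer pairs unique", False,
                      f"{r.id} duplicates {pairs[key]}")
            pairs[key] = r.id

        matrix = reactivity_matrix(panel, locus)
        for a in matrix.alleles:
            check(f"{locus} allele {a} has >=1 positive reaction", matrix.row(a).any())

    for p in panel.primers.values():
        if not 14 <= len(p.sequence) <= 31:
            check(f"primer {p.name} length 14-31", False, f"len={len(p.sequence)}")
        if p.lna_positions and min(p.lna_positions) < len(p.sequence) - 2:
            check(f"primer {p.name} LNA at/adjacent to 3' end", False,
                  f"positions {sorted(p.lna_positions)}")
        span_len = p.ref_span[1] - p.ref_span[0] + 1
        if span_len != len(p.sequence):
            # stored verbatim from the source tables; flagged, never failed
            warnings.append(
                f"primer {p.name}: printed span {p.ref_span[0]}-{p.ref_span[1]} "
                f"({span_len} nt) inconsistent with {len(p.sequence)}-mer sequence"
            )

    return PanelAudit(
        primer_counts=primer_counts,
        probe_counts=probe_counts,
        total_probes=total_probes,
        reaction_counts=reaction_counts,
        allele_counts=allele_counts,
        total_alleles=total_alleles,
        checks=checks,
        warnings=warnings,
    )
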