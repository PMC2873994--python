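"""Simulation and fixture generators.

Everything the other modules need for testing with no external downloads:
genotype tables drawn under Hardy-Weinberg equilibrium, Ct plates with a
configurable noise model reproducing the bimodal carrier/non-carrier
separation, and synthetic allele templates plus toy panels that realize an
arbitrary target reactivity matrix for the in-silico predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .insilico_ssp import AlleleSequence, MatchRules, predict_matrix, reverse_complement
from .panel_model import Panel, Primer, Probe, Reaction, ReactivityMatrix
from .typing_engine import CT_MAX, CtRecord

__all__ = [
    "NoiseModel",
    "simulate_population",
    "simulate_ct_plate",
    "make_fixture_panel",
    "make_fixture_alleles",
]


@dataclass(frozen=True)
class NoiseModel:
    """Ct noise parameters; all Ct values are clipped to [0, 60]."""

    internal_ct_mean: float = 24.0
    internal_ct_sd: float = 0.7
    reactive_delta_mean: float = 1.0
    reactive_delta_sd: float = 0.5
    nonreactive_undetermined_prob: float = 0.8
    nonreactive_delta_mean: float = 15.0
    nonreactive_delta_sd: float = 2.0
    dropout_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("internal_ct_sd", "reactive_delta_sd", "nonreactive_delta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nonreactive_undetermined_prob", "dropout_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


NOISE_FREE = NoiseModel(internal_ct_sd=0.0, reactive_delta_sd=0.0,
                        nonreactive_undetermined_prob=1.0, nonreactive_delta_sd=0.0)


def simulate_population(
    freqs: Mapping[str, Mapping[str, float]],
    n_samples: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw genotypes under Hardy-Weinberg equilibrium.

    ``freqs`` maps locus -> allele -> frequency (each locus must sum to 1);
    each sample receives two i.i.d. allele copies per locus.  Returns a table
    with columns ``sample_id, locus, allele_1, allele_2``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for locus, table in freqs.items():
        total = sum(table.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{locus}: frequencies sum to {total}, not 1")
        if any(f < 0 for f in table.values()):
            raise ValueError(f"{locus}: negative frequency")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_samples)))
    rows = []
    for locus in sorted(freqs):
        alleles = sorted(freqs[locus])
        p = np.array([freqs[locus][a] for a in alleles])
        p = p / p.sum()
        draws = rng.choice(len(alleles), size=(n_samples, 2), p=p)
        for i, (x, y) in enumerate(draws, start=1):
            a, b = sorted((alleles[x], alleles[y]))
            rows.append((f"S{i:0{width}d}", locus, a, b))
    return pd.DataFrame(rows, columns=["sample_id", "locus", "allele_1", "allele_2"])


def simulate_ct_plate(
    genotypes: pd.DataFrame,
    panel: Panel,
    matrix: ReactivityMatrix,
    noise: NoiseModel = NoiseModel(),
) -> list[CtRecord]:
    """Emulate a Ct plate for the genotype rows matching ``matrix.locus``.

    Reactions in a genotype's union pattern get a small delta-Ct; the rest
    either never cross the threshold (Ct 60) or show a large delta.  Dropout
    replaces the internal-standard Ct with 60, invalidating the reaction.
    """
    rng = np.random.default_rng(noise.seed)
    rows = genotypes[genotypes["locus"] == matrix.locus]
    known = set(matrix.alleles)
    records: list[CtRecord] = []

    def clip(x: float) -> float:
        return float(min(max(x, 0.0), CT_MAX))

    for row in rows.itertuples():
        for a in (row.allele_1, row.allele_2):
            if a not in known:
                raise KeyError(f"allele {a!r} not in {matrix.locus} matrix")
        pattern = matrix.row(row.allele_1) | matrix.row(row.allele_2)
        for j, reaction_id in enumerate(matrix.reactions):
            ct_int = clip(rng.normal(noise.internal_ct_mean, noise.internal_ct_sd))
            if noise.dropout_prob and rng.random() < noise.dropout_prob:
                ct_int = CT_MAX
            if pattern[j]:
                ct_spec = clip(ct_int + rng.normal(noise.reactive_delta_mean,
                                                   noise.reactive_delta_sd))
            elif rng.random() < noise.nonreactive_undetermined_prob:
                ct_spec = CT_MAX
            else:
                ct_spec = clip(ct_int + rng.normal(noise.nonreactive_delta_mean,
                                                   noise.nonreactive_delta_sd))
            records.append(CtRecord(row.sample_id, reaction_id, ct_spec, ct_int))
    return records


# ---------------------------------------------------------------------------
# In-silico fixtures
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_fixture_panel(
    n_reactions: int,
    seed: int | None = None,
    locus: str = "SYN",
) -> Panel:
    """Toy single-locus panel with random oligos, for predictor fixtures.

    Each reaction gets its own specific primer pair and FAM probe; one shared
    internal-standard primer pair and TET probe serve every reaction.
    """
    rng = np.random.default_rng(seed)
    panel = Panel()
    panel.reactions[locus] = []
    panel.alleles[locus] = []
    primers: dict[str, Primer] = {}
    probes: dict[str, Probe] = {}

    def add_primer(name: str, orientation: str, span: tuple[int, int]) -> str:
        primers[name] = Primer(name, _random_seq(rng, 20), frozenset(),
                               orientation, locus, span)
        return name

    def add_probe(name: str, dye: str, span: tuple[int, int]) -> str:
        probes[name] = Probe(name, dye, "BHQ1", _random_seq(rng, 24), locus, span)
        return name

    int_fwd = add_primer("SYNIF01", "forward", (700, 719))
    int_rev = add_primer("SYNIR01", "reverse", (780, 799))
    int_probe = add_probe("SYNIP01", "TET", (740, 763))
    for k in range(1, n_reactions + 1):
        sf = add_primer(f"SYN{k:03d}F", "forward", (100, 119))
        sr = add_primer(f"SYN{k:03d}R", "reverse", (180, 199))
        sp = add_probe(f"SYN{k:03d}P", "FAM", (140, 163))
        panel.reactions[locus].append(Reaction(
            f"{locus} {k:03d}", locus, sf, sr, sp, int_fwd, int_rev, int_probe,
            frozenset({"pending"}),
        ))
    panel.primers = primers
    panel.probes = probes
    return panel


def make_fixture_alleles(
    target: ReactivityMatrix,
    panel: Panel,
    seed: int | None = None,
    spacer: int = 6,
) -> list[AlleleSequence]:
    """Synthetic templates realizing a target reactivity matrix.

    Every template carries the internal-standard sites; each reaction's
    specific block is embedded intact for cells marked true and with the
    specific forward primer's 3'-terminal template base mutated for cells
    marked false.  The construction is verified with the predictor itself and
    an unrealizable target raises ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    locus = target.locus
    if locus not in panel.reactions:
        raise KeyError(f"locus {locus!r} not in panel")
    reactions = panel.reactions[locus]
    rxn_by_id = {r.id: r for r in reactions}
    missing = [r for r in target.reactions if r not in rxn_by_id]
    if missing:
        raise KeyError(f"target reactions not in panel: {missing}")

    def block(fwd: Primer, rev: Primer, probe: Probe, mutate_fwd: bool) -> str:
        fseq = fwd.sequence
        if mutate_fwd:
            last = fseq[-1]
            fseq = fseq[:-1] + rng.choice([b for b in "ACGT" if b != last])
        gap1 = _random_seq(rng, spacer)
        gap2 = _random_seq(rng, spacer)
        return fseq + gap1 + probe.sequence + gap2 + reverse_complement(rev.sequence)

    internal_trios = []
    for rid in target.reactions:
        rxn = rxn_by_id[rid]
        trio = (rxn.internal_fwd, rxn.internal_rev, rxn.internal_probe)
        if trio not in internal_trios:
            internal_trios.append(trio)

    out: list[AlleleSequence] = []
    for allele in target.alleles:
        parts = [_random_seq(rng, spacer)]
        for fwd, rev, probe in internal_trios:
            parts.append(block(panel.primers[fwd], panel.primers[rev],
                               panel.probes[probe], False))
            parts.append(_random_seq(rng, spacer))
        for rid in target.reactions:
            rxn = rxn_by_id[rid]
            parts.append(block(panel.primers[rxn.specific_fwd],
                               panel.primers[rxn.specific_rev],
                               panel.probes[rxn.specific_probe],
                               mutate_fwd=not target.cell(allele, rid)))
            parts.append(_random_seq(rng, spacer))
        out.append(AlleleSequence(allele, "".join(parts)))

    prediction = predict_matrix(out, panel, locus, MatchRules(), curated=target)
    if prediction.discrepancies:
        raise ValueError(
            "unrealizable target matrix; conflicting cells: "
            + ", ".join(f"{a}/{r}" for a, r, _, _ in prediction.discrepancies)
        )
    if not all(prediction.internal_valid.values()):
        raise ValueError("internal-standard sites failed verification")
    return out
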