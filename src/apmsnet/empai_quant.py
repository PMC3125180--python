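"""emPAI abundance from peptide identifications.

emPAI (exponentially modified Protein Abundance Index) estimates relative
protein abundance from the ratio of distinct observed tryptic peptides to
the number of observable ones:

    emPAI = 10^(N_observed / N_observable) - 1

Observable peptides come from an in-silico tryptic digest (cleavage
C-terminal to K or R, suppressed before proline) with a configurable
number of missed cleavages, filtered by peptide length and optionally by
monoisotopic mass.  The observable-peptide criterion used by search
engines varies; here it is explicit configuration, defaulting to fully
tryptic peptides of 6-30 residues with at most one missed cleavage and no
mass filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .io_formats import PulldownMatrix

# Monoisotopic residue masses (Da); peptide mass = sum + water.
MONOISOTOPIC_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MASS = 18.01056

VALID_RESIDUES = set(MONOISOTOPIC_MASS) | {"X"}


class UndefinedAbundanceError(ValueError):
    """emPAI is undefined when a protein has no observable peptides."""


@dataclass
class EmpaiParams:
    """Digestion and observable-peptide filter settings.

    missed_cleavages : allowed missed tryptic sites (default 1, matching
        a fully-tryptic search with up to one missed cleavage).
    min_len / max_len : peptide length bounds in residues (default 6-30).
    min_mass / max_mass : monoisotopic mass bounds in Da (default none).
    """

    missed_cleavages: int = 1
    min_len: int = 6
    max_len: int = 30
    min_mass: float = 0.0
    max_mass: float = math.inf

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.min_mass > self.max_mass:
            raise ValueError("min_mass > max_mass")


@dataclass
class PeptideObservation:
    """One identified peptide in one (bait, replicate, fraction) run."""

    protein_id: str
    peptide_sequence: str
    bait_id: str
    replicate_id: int
    fraction_id: int

    def __post_init__(self) -> None:
        seq = self.peptide_sequence
        if not seq:
            raise ValueError("empty peptide sequence")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in peptide {seq!r}")


def peptide_mass(sequence: str) -> float | None:
    """Monoisotopic peptide mass, or None when 'X' makes it undefined."""
    if "X" in sequence:
        return None
    return sum(MONOISOTOPIC_MASS[r] for r in sequence) + WATER_MASS


def _cleavage_sites(sequence: str) -> list[int]:
    # positions after which trypsin cuts: K/R not followed by P
    return [
        i + 1
        for i, res in enumerate(sequence[:-1])
        if res in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, params: EmpaiParams | None = None) -> set[str]:
    """In-silico tryptic digest of a protein sequence.

    Cleaves C-terminal to K or R except before proline, and returns all
    distinct products with up to ``params.missed_cleavages`` internal
    missed sites, including the terminal peptides.  Length/mass filters
    are NOT applied here (see :func:`count_observable`).
    """
    params = params or EmpaiParams()
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in protein sequence")
    bounds = [0] + _cleavage_sites(sequence) + [len(sequence)]
    peptides: set[str] = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + params.missed_cleavages, len(bounds))):
            peptides.add(sequence[bounds[i]:bounds[j]])
    return peptides


def _passes_filters(peptide: str, params: EmpaiParams) -> bool:
    if not (params.min_len <= len(peptide) <= params.max_len):
        return False
    if params.min_mass > 0 or math.isfinite(params.max_mass):
        mass = peptide_mass(peptide)
        if mass is None:  # 'X' residues disqualify mass filtering
            return False
        if not (params.min_mass <= mass <= params.max_mass):
            return False
    return True


def count_observable(sequence: str, params: EmpaiParams | None = None) -> int:
    """Number of distinct digestion products passing the length/mass filters."""
    params = params or EmpaiParams()
    return sum(1 for p in digest(sequence, params) if _passes_filters(p, params))


def compute_empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(N_observed / N_observable) - 1.

    ``n_observed`` is capped at ``n_observable`` before the ratio, so the
    ratio never exceeds 1 and emPAI never exceeds 9 (modified or extra
    missed-cleavage variants can otherwise push the observed count past
    the nominal observable count).
    """
    if n_observable < 1:
        raise UndefinedAbundanceError("protein has no observable peptides")
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    ratio = min(n_observed, n_observable) / n_observable
    return 10.0 ** ratio - 1.0


def quantify(observations: Iterable[PeptideObservation],
             proteome_fasta: str | dict[str, str],
             params: EmpaiParams | None = None,
             strict: bool = True) -> PulldownMatrix:
    """emPAI matrix from peptide observations and a proteome.

    Observed peptides are counted as distinct sequences per
    (protein, bait, replicate, fraction) cell, so charge states and
    modified forms of one peptide collapse to a single observation.
    ``proteome_fasta`` is a FASTA path or an in-memory id->sequence map.
    With ``strict`` (default), an observed peptide that is not a product
    of its protein's digest raises; otherwise it is counted anyway.
    """
    params = params or EmpaiParams()
    if isinstance(proteome_fasta, dict):
        proteome = proteome_fasta
    else:
        proteome = {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(proteome_fasta, "fasta")}

    digests: dict[str, set[str]] = {}
    observable: dict[str, int] = {}
    cells: dict[tuple[str, str, int, int], set[str]] = {}
    for obs in observations:
        if obs.protein_id not in proteome:
            raise KeyError(f"protein {obs.protein_id!r} absent from proteome FASTA")
        if obs.protein_id not in digests:
            seq = proteome[obs.protein_id]
            digests[obs.protein_id] = digest(seq, params)
            observable[obs.protein_id] = count_observable(seq, params)
        if strict and obs.peptide_sequence not in digests[obs.protein_id]:
            raise ValueError(
                f"peptide {obs.peptide_sequence!r} is not a digestion product "
                f"of protein {obs.protein_id!r}"
            )
        key = (obs.protein_id, obs.bait_id, obs.replicate_id, obs.fraction_id)
        cells.setdefault(key, set()).add(obs.peptide_sequence)

    entries = {
        key: compute_empai(len(peptides), observable[key[0]])
        for key, peptides in cells.items()
    }
    return PulldownMatrix(entries)
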