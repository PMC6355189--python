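"""Modified-peptide chemistry: parsing, theoretical masses, coverage audits.

The synthetic CD160 fragments studied here are solid-phase peptides with
optional N-terminal acetylation, C-terminal amidation, cysteine-to-Abu
(2-aminobutyric acid) substitutions, and optional linker moieties
(penta-glycine, biotin) for ELISA immobilization.  This module turns the
bench notation (``Ac-RLNLIAbuTVWHKKEEAEGFVV-NH2``) into typed objects,
computes elemental formulas and theoretical masses, and audits a peptide
map's coverage and redundancy against the parent protein.

Two mass conventions are exposed.  ``average_mass`` is the isotope-averaged
neutral molecular mass, which is the quantity tabulated as the "calculated
mass" for these constructs (it reproduces the printed values within
0.05 Da); ``monoisotopic_mass`` and ``ion_mz`` serve the monoisotopic
[M+H]+/[M+Na]+ values read off the spectra.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import (
    ACETYL_DELTA,
    AMIDE_DELTA,
    AVERAGE_MASS,
    CANONICAL_RESIDUES,
    CATION_MASS,
    MOIETY_FORMULA,
    MONOISOTOPIC_MASS,
    RESIDUE_FORMULA,
    WATER,
    mass_of_formula,
)

__all__ = [
    "ProteinSequence",
    "ModifiedPeptide",
    "MassResult",
    "CoverageReport",
    "PeptideParseError",
    "parse_peptide",
    "render_peptide",
    "elemental_formula",
    "average_mass",
    "monoisotopic_mass",
    "mass_result",
    "ion_mz",
    "coverage_stats",
    "read_fasta",
    "read_peptide_table",
    "write_peptide_table",
]


class PeptideParseError(ValueError):
    """Raised when a peptide spec cannot be reconciled with its parent."""


@dataclass(frozen=True)
class ProteinSequence:
    """A parent protein sequence with mature-protein numbering.

    ``numbering_offset`` is the 1-based index of the first stored residue in
    the mature protein, so residue *i* of the mature numbering is
    ``residues[i - numbering_offset]``.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residues in {self.id!r}: {sorted(bad)}")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, index: int) -> str:
        """One-letter code at mature-protein position ``index`` (1-based)."""
        i = index - self.numbering_offset
        if not 0 <= i < len(self.residues):
            raise IndexError(f"residue {index} outside {self.id} bounds")
        return self.residues[i]


@dataclass(frozen=True)
class ModifiedPeptide:
    """A parent-protein interval with substitutions and terminal mods.

    ``sequence`` uses one-letter codes with ``B`` for Abu.  ``substitutions``
    maps mature-protein positions to ``(parent_residue, new_residue)``.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    n_term_mod: str = "free"        # {"free", "acetyl"}
    c_term_mod: str = "free_acid"   # {"free_acid", "amide"}
    linker: tuple[str, ...] = ()
    substitutions: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match interval "
                f"{self.start}-{self.end}"
            )
        if self.n_term_mod not in ("free", "acetyl"):
            raise ValueError(f"unknown n_term_mod {self.n_term_mod!r}")
        if self.c_term_mod not in ("free_acid", "amide"):
            raise ValueError(f"unknown c_term_mod {self.c_term_mod!r}")
        unknown = [r for r in self.sequence if r not in RESIDUE_FORMULA]
        if unknown:
            raise ValueError(f"unknown residue letters: {unknown}")
        for moiety in self.linker:
            if moiety not in MOIETY_FORMULA:
                raise ValueError(f"unknown linker moiety {moiety!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MassResult:
    monoisotopic_neutral: float
    average_neutral: float
    formula: dict[str, int]


@dataclass(frozen=True)
class CoverageReport:
    """Coverage of a parent sequence by a peptide map.

    ``mean_redundancy`` is the mean per-residue depth over *covered* residues
    and is ``None`` when nothing is covered.
    """

    percent_coverage: float
    mean_redundancy: float | None
    per_residue_depth: np.ndarray


_SPEC_RE = re.compile(r"^(?P<ac>Ac-)?(?P<body>[A-Za-z]+?)(?P<am>-NH_?2_?)?$")


def parse_peptide(
    spec: str,
    parent: ProteinSequence | None = None,
    start: int | None = None,
    end: int | None = None,
    linker: Sequence[str] = (),
) -> ModifiedPeptide:
    """Parse bench notation into a :class:`ModifiedPeptide`.

    ``Ac-`` marks N-terminal acetylation, a ``-NH2``/``-NH_2_`` suffix marks
    C-terminal amidation, and the inline token ``Abu`` marks a
    2-aminobutyric-acid substitution.  When ``parent`` is given, every
    non-substituted position must match the parent sequence; Abu is accepted
    as a substitution of any parent residue (in practice cysteine) and the
    substitution is recorded against mature-protein numbering.
    """
    m = _SPEC_RE.match(spec.strip())
    if m is None:
        raise PeptideParseError(f"cannot parse peptide spec {spec!r}")
    n_term = "acetyl" if m.group("ac") else "free"
    c_term = "amide" if m.group("am") else "free_acid"

    body = m.group("body")
    residues: list[str] = []
    i = 0
    while i < len(body):
        if body[i : i + 3] == "Abu":
            residues.append("B")
            i += 3
            continue
        ch = body[i]
        if ch not in CANONICAL_RESIDUES:
            raise PeptideParseError(f"unknown token at position {i} in {spec!r}")
        residues.append(ch)
        i += 1
    seq = "".join(residues)

    if start is None or end is None:
        if parent is not None:
            raise PeptideParseError("start and end required when parent is given")
        start, end = 1, len(seq)
    if end - start + 1 != len(seq):
        raise PeptideParseError(
            f"interval {start}-{end} does not match parsed length {len(seq)}"
        )

    substitutions: dict[int, tuple[str, str]] = {}
    parent_id = parent.id if parent is not None else "unknown"
    if parent is not None:
        for offset, res in enumerate(seq):
            pos = start + offset
            expected = parent.residue_at(pos)
            if res == expected:
                continue
            if res == "B":
                substitutions[pos] = (expected, "B")
            else:
                raise PeptideParseError(
                    f"residue mismatch at position {pos}: spec has {res!r}, "
                    f"parent {parent.id} has {expected!r}"
                )

    return ModifiedPeptide(
        parent_id=parent_id,
        start=start,
        end=end,
        sequence=seq,
        n_term_mod=n_term,
        c_term_mod=c_term,
        linker=tuple(linker),
        substitutions=substitutions,
    )


def render_peptide(p: ModifiedPeptide) -> str:
    """Canonical bench notation for a peptide (round-trips with the parser)."""
    body = "".join("Abu" if r == "B" else r for r in p.sequence)
    prefix = "Ac-" if p.n_term_mod == "acetyl" else ""
    suffix = "-NH2" if p.c_term_mod == "amide" else ""
    return f"{prefix}{body}{suffix}"


def elemental_formula(p: ModifiedPeptide) -> dict[str, int]:
    """Elemental composition of the neutral molecule.

    Sum of residue compositions plus one water, adjusted for terminal
    modifications, plus any linker moieties (already condensed).
    """
    counts: Counter[str] = Counter()
    for res in p.sequence:
        counts.update(RESIDUE_FORMULA[res])
    counts.update(WATER)
    if p.n_term_mod == "acetyl":
        counts.update(ACETYL_DELTA)
    if p.c_term_mod == "amide":
        for el, d in AMIDE_DELTA.items():
            counts[el] += d
    for moiety in p.linker:
        counts.update(MOIETY_FORMULA[moiety])
    return {el: n for el, n in sorted(counts.items()) if n != 0}


def average_mass(p: ModifiedPeptide) -> float:
    """Isotope-averaged neutral molecular mass, Da."""
    return mass_of_formula(elemental_formula(p), AVERAGE_MASS)


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Monoisotopic neutral molecular mass, Da."""
    return mass_of_formula(elemental_formula(p), MONOISOTOPIC_MASS)


def mass_result(p: ModifiedPeptide) -> MassResult:
    f = elemental_formula(p)
    return MassResult(
        monoisotopic_neutral=mass_of_formula(f, MONOISOTOPIC_MASS),
        average_neutral=mass_of_formula(f, AVERAGE_MASS),
        formula=f,
    )


def ion_mz(p: ModifiedPeptide, adduct: str = "proton", charge: int = 1) -> float:
    """Monoisotopic m/z of ``[M + n·adduct]^n+``.

    Cation masses (H+ 1.00728, Na+ 22.98922) already account for the
    electron, so no further electron-mass correction is applied.
    """
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    if adduct not in CATION_MASS:
        raise ValueError(f"unknown adduct {adduct!r}")
    return (monoisotopic_mass(p) + charge * CATION_MASS[adduct]) / charge


def coverage_stats(
    peptides: Iterable[ModifiedPeptide | tuple[int, int]],
    parent: ProteinSequence,
) -> CoverageReport:
    """Per-residue depth, percent coverage and mean redundancy of a map."""
    off = parent.numbering_offset
    n = len(parent)
    depth = np.zeros(n, dtype=int)
    for pep in peptides:
        start, end = (pep.start, pep.end) if isinstance(pep, ModifiedPeptide) else pep
        if start < off or end > off + n - 1:
            raise ValueError(f"peptide {start}-{end} outside parent bounds")
        depth[start - off : end - off + 1] += 1
    covered = depth > 0
    pct = 100.0 * covered.sum() / n
    redundancy = float(depth[covered].mean()) if covered.any() else None
    return CoverageReport(
        percent_coverage=pct, mean_redundancy=redundancy, per_residue_depth=depth
    )


# ---------------------------------------------------------------------------
# External interfaces


def read_fasta(path: str | Path, numbering_offset: int = 1) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper(),
                        numbering_offset=numbering_offset)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


PEPTIDE_TABLE_COLUMNS = ["name", "start", "end", "sequence_spec", "n_term", "c_term"]


def read_peptide_table(
    path: str | Path, parent: ProteinSequence | None = None
) -> list[tuple[str, ModifiedPeptide]]:
    """Read a delimited peptide table (columns: name, start, end,
    sequence_spec, n_term, c_term) and parse each row."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PEPTIDE_TABLE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        pep = parse_peptide(
            str(row["sequence_spec"]),
            parent=parent,
            start=int(row["start"]),
            end=int(row["end"]),
        )
        out.append((str(row["name"]), pep))
    return out


def write_peptide_table(
    peptides: Iterable[tuple[str, ModifiedPeptide]], path: str | Path
) -> None:
    rows = [
        {
            "name": name,
            "start": p.start,
            "end": p.end,
            "sequence_spec": render_peptide(p),
            "n_term": p.n_term_mod,
            "c_term": p.c_term_mod,
        }
        for name, p in peptides
    ]
    pd.DataFrame(rows, columns=PEPTIDE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
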