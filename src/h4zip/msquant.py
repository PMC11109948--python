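"""Targeted-MS quantification of H4 tail acetylation motifs.

The assay measures the tryptic H4 peptide spanning G4–R17 (G4–R16 for the
K16R mutant).  Before digestion, every lysine that was *not* enzymatically
acetylated is chemically acetylated with acetic anhydride-D6, which adds a
heavy D3-acetyl group 3.0188 Da heavier than the enzymatic (light) acetyl.
Each peptide species therefore carries ``n_light + n_heavy = n_lysines``
acetyl groups, and the light/heavy composition encodes the motif.  Relative
motif abundances are MS1 peak-area fractions of the summed areas over all
species of the peptide; motifs below the 0.003% detection limit are flagged
(strict "below", never zeroed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .motifs import Motif, parse_motif_label

__all__ = [
    "MASS_CONSTANTS",
    "PEPTIDE_SEQUENCES",
    "REFERENCE_MZ",
    "PeptideSpecies",
    "PeakTable",
    "AbundanceTable",
    "species_for_motif",
    "theoretical_mz",
    "relative_abundance",
    "apply_detection_limit",
    "read_peak_table",
]

#: Editable mass-constant table (monoisotopic, Da).  Residue masses come
#: from pyteomics' standard table; only the modification chemistry lives here.
MASS_CONSTANTS: dict[str, float] = {
    "acetyl_light": 42.010565,   # enzymatic CH3CO-
    "acetyl_heavy_d3": 45.029395,  # chemical CD3CO- from acetic anhydride-D6
    "proton": 1.007276,
}

#: Tryptic H4 tail peptides (Drosophila H4 residues; the tail sequence is
#: invariant across metazoa).  K16R truncates the peptide at the new R16.
PEPTIDE_SEQUENCES: dict[str, str] = {
    "wildtype_G4R17": "GKGGKGLGKGGAKR",  # G4..R17, lysines K5 K8 K12 K16
    "k16r_G4R16": "GKGGKGLGKGGAR",       # G4..R16, lysines K5 K8 K12
}

_SEQUENCE_SITES: dict[str, tuple[str, ...]] = {
    "wildtype_G4R17": ("K5", "K8", "K12", "K16"),
    "k16r_G4R16": ("K5", "K8", "K12"),
}

#: Published doubly-protonated m/z values, kept as reference metadata.  They
#: differ from the standard monoisotopic computation for the stated acetyl
#: composition by ~1 Da at neutral mass (origin unstated); ``theoretical_mz``
#: always reports the computed value.
REFERENCE_MZ: dict[tuple[str, int], float] = {
    ("wildtype_G4R17", 1): 724.9428,  # mono-enzymatic (n_light = 1)
    ("wildtype_G4R17", 2): 723.4329,  # di-enzymatic
    ("wildtype_G4R17", 3): 721.9221,  # tri-enzymatic
    ("k16r_G4R16", 1): 637.8759,
    ("k16r_G4R16", 2): 636.3665,
    ("k16r_G4R16", 3): 634.8571,
}

#: Heavy-minus-light acetyl mass difference ("mass difference of three Daltons").
HEAVY_LIGHT_DELTA = MASS_CONSTANTS["acetyl_heavy_d3"] - MASS_CONSTANTS["acetyl_light"]


@dataclass(frozen=True)
class PeptideSpecies:
    """One light/heavy acetyl composition of an H4 tail peptide."""

    sequence_id: str
    motif: Motif
    n_light: int
    n_heavy: int
    charge: int = 2

    def __post_init__(self):
        if self.sequence_id not in PEPTIDE_SEQUENCES:
            raise ValueError(f"unknown sequence_id {self.sequence_id!r}")
        n_lys = PEPTIDE_SEQUENCES[self.sequence_id].count("K")
        if self.n_light + self.n_heavy != n_lys:
            raise ValueError(
                f"acetyl bookkeeping violated: {self.n_light}+{self.n_heavy} != {n_lys} lysines"
            )


def species_for_motif(m: Motif, sequence_id: str = "wildtype_G4R17", charge: int = 2) -> PeptideSpecies:
    """Map a motif to its peptide species: enzymatic acetyls are light, and
    chemical derivatization converts every remaining lysine to heavy."""
    if sequence_id not in PEPTIDE_SEQUENCES:
        raise ValueError(f"unknown sequence_id {sequence_id!r}")
    sites = _SEQUENCE_SITES[sequence_id]
    bad = [s for s in m.acetylated_sites if s not in sites]
    if bad:
        raise ValueError(f"motif sites {bad} not present in sequence {sequence_id!r}")
    n_lys = len(sites)
    n_light = m.acetyl_count
    return PeptideSpecies(sequence_id, m, n_light, n_lys - n_light, charge)


def theoretical_mz(sp: PeptideSpecies) -> float:
    """Monoisotopic m/z of a peptide species at its charge.

    Neutral mass = residue masses + water (via pyteomics) + light and heavy
    acetyl masses; the peptide N-terminal amine is unmodified (derivatization
    precedes digestion, so the new N-terminus is never chemically acetylated).
    """
    if sp.charge < 1:
        raise ValueError("charge must be >= 1")
    seq = PEPTIDE_SEQUENCES[sp.sequence_id]
    neutral = (
        _pmass.calculate_mass(sequence=seq)
        + sp.n_light * MASS_CONSTANTS["acetyl_light"]
        + sp.n_heavy * MASS_CONSTANTS["acetyl_heavy_d3"]
    )
    return (neutral + sp.charge * MASS_CONSTANTS["proton"]) / sp.charge


# --- peak tables and relative abundances -----------------------------------

#: Required columns of a peak table (long format, one row per species
#: per time point per replicate).
PEAK_TABLE_COLUMNS = ["sequence_id", "motif_label", "charge", "time_min", "replicate", "ms1_area"]


@dataclass
class PeakTable:
    """MS1 peak areas for the species of one peptide sequence."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PEAK_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if (self.df["ms1_area"] < 0).any():
            raise ValueError("MS1 areas must be non-negative")
        dup = self.df.duplicated(subset=["motif_label", "time_min", "replicate"])
        if dup.any():
            raise ValueError("at most one row per species per replicate/time")

    @property
    def sequence_ids(self) -> list[str]:
        return sorted(self.df["sequence_id"].unique())


def read_peak_table(path) -> PeakTable:
    return PeakTable(pd.read_csv(path))


@dataclass
class AbundanceTable:
    """Relative motif abundances with detection-limit flags.

    ``df`` is long format with columns (motif_label, time_min, replicate, y,
    masked).  Abundances sum to 1 per (time, replicate) before masking;
    masking is a reporting flag, never a zeroing.
    """

    df: pd.DataFrame
    detection_limit: float = 3e-5
    motifs: list[str] = field(default_factory=list)

    def pivot(self) -> pd.DataFrame:
        """Motif x (time, replicate) wide table of abundances."""
        return self.df.pivot_table(
            index="motif_label", columns=["time_min", "replicate"], values="y", sort=False
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def relative_abundance(pt: PeakTable, motifs: list[str] | None = None) -> AbundanceTable:
    """Convert MS1 peak areas to relative motif abundances.

    Each species' area is divided by the summed area of *all* H4 species
    (unmodified and modified) of the same replicate and time point.  Motifs
    absent from the table are treated as area 0 only if listed in ``motifs``.
    """
    if len(pt.sequence_ids) != 1:
        raise ValueError(f"peak table must cover one sequence_id, got {pt.sequence_ids}")
    seq_id = pt.sequence_ids[0]
    sites = _SEQUENCE_SITES[seq_id]

    rows = []
    for (t, r), grp in pt.df.groupby(["time_min", "replicate"], sort=True):
        total = grp["ms1_area"].sum()
        if total <= 0:
            raise ValueError(f"total MS1 area is zero at time={t}, replicate={r}")
        present = dict(zip(grp["motif_label"], grp["ms1_area"] / total))
        labels = motifs if motifs is not None else list(grp["motif_label"])
        for lab in labels:
            canon = parse_motif_label(str(lab), sites).label
            rows.append(
                {"motif_label": canon, "time_min": t, "replicate": r,
                 "y": float(present.get(lab, 0.0)), "masked": False}
            )
    df = pd.DataFrame(rows)
    return AbundanceTable(df=df, motifs=list(dict.fromkeys(df["motif_label"])))


def apply_detection_limit(at: AbundanceTable, limit: float = 3e-5) -> AbundanceTable:
    """Flag abundances strictly below the detection limit (default 0.003%).

    Values are preserved; only the ``masked`` flag changes, so downstream
    fitting can choose between omitting and censoring.  Idempotent.
    """
    if not 0 < limit < 1:
        raise ValueError("detection limit must be in (0, 1)")
    df = at.df.copy()
    df["masked"] = df["y"] < limit
    return replace(at, df=df, detection_limit=limit)
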