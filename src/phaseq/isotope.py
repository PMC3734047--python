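"""13C incorporation into P(3HB) from GC-MS mass-isotopomer distributions.

Methanolysis of poly(3-hydroxybutyrate) yields 3HB methyl ester, whose
electron-impact fragments at m/z 45 (CH3-CH=OH+, 2 carbons), m/z 87
(CH3-C(OH)H-CH2-C=O+, 4 carbons) and m/z 103 (CH3-O-CO-CH2-CH=OH+, 4
carbons as written, one carbon contributed by the derivatisation methanol)
carry the polymer's carbon. From each fragment's mass-isotopomer
distribution (MID, relative abundances M0..Mn) the 13C atom fraction is the
MID mean divided by the carbon count; the unweighted mean over the three
fragments, in percent, is the 13C abundance of the P(3HB) fraction.

The incorporation increase subtracts the matched unlabelled-bicarbonate
control culture (which also absorbs natural-abundance background — no
separate natural-abundance correction is applied) and converts the atom
fraction difference to mmol 13C per gram of polymer:

    increase = delta * n_C / M * 1000

with n_C the mean fragment carbon count (10/3 for the three fragments) and
M = 86.09 g/mol the C4H6O2 repeat unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHB_MONOMER_MASS = 86.09  # g/mol, C4H6O2 repeat unit


class SpectrumError(ValueError):
    """Unusable mass-isotopomer spectrum."""


@dataclass(frozen=True)
class FragmentSpec:
    """A GC-MS fragment ion and its carbon count."""

    label: str
    n_carbons: int

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")


#: The three 3HB methyl ester fragments used for quantification.
HB_FRAGMENTS: tuple[FragmentSpec, ...] = (
    FragmentSpec("mz45", 2),
    FragmentSpec("mz87", 4),
    FragmentSpec("mz103", 4),
)


@dataclass(frozen=True)
class MonomerSpec:
    name: str
    molar_mass: float  # g/mol
    n_carbons: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")


PHB = MonomerSpec("P(3HB)", PHB_MONOMER_MASS, 4)


@dataclass
class FragmentMID:
    """A fragment's mass-isotopomer abundance vector M0..Mn, stored normalised.

    Abundances beyond M(n_carbons) are dropped with a warning before
    normalisation (they arise from heavier-isotope channels the binomial
    carbon model does not cover).
    """

    fragment: FragmentSpec
    abundances: np.ndarray

    def __post_init__(self) -> None:
        abund = np.asarray(self.abundances, dtype=float)
        expected = self.fragment.n_carbons + 1
        if abund.size > expected:
            import warnings

            warnings.warn(
                f"{self.fragment.label}: dropping {abund.size - expected} "
                "channel(s) beyond M+n_carbons", stacklevel=2,
            )
            abund = abund[:expected]
        if abund.size != expected:
            raise SpectrumError(
                f"{self.fragment.label}: expected {expected} channels, "
                f"got {abund.size}"
            )
        if (abund < 0).any():
            raise SpectrumError(f"{self.fragment.label}: negative abundance")
        total = abund.sum()
        if total <= 0:
            raise SpectrumError(f"{self.fragment.label}: all-zero spectrum")
        self.abundances = abund / total


def atom_fraction(mid: FragmentMID) -> float:
    """Average fraction of labelled carbon positions in the fragment.

    Sum_i i*Mi is the mean number of 13C atoms; dividing by the carbon count
    gives the per-position labelling probability. For an exact binomial MID
    this recovers p exactly.
    """
    n = mid.fragment.n_carbons
    i = np.arange(n + 1)
    return float((i * mid.abundances).sum() / n)


def mean_abundance(mids: Sequence[FragmentMID]) -> float:
    """Unweighted mean of per-fragment atom fractions, in percent."""
    if not mids:
        raise ValueError("need at least one fragment MID")
    return 100.0 * float(np.mean([atom_fraction(m) for m in mids]))


@dataclass
class IncorporationResult:
    """13C incorporation of one strain relative to its unlabelled control."""

    strain: str
    abundance_labeled: float  # percent
    abundance_control: float  # percent
    delta: float = field(init=False)       # atom fraction
    increase: float = field(init=False)    # mmol 13C per g polymer

    mean_fragment_carbons: float = float(np.mean([f.n_carbons for f in HB_FRAGMENTS]))
    monomer: MonomerSpec = PHB

    def __post_init__(self) -> None:
        self.delta = (self.abundance_labeled - self.abundance_control) / 100.0
        self.increase = (
            self.delta * self.mean_fragment_carbons / self.monomer.molar_mass * 1000.0
        )

    @property
    def increase_reported(self) -> float:
        """The increase at the 2-decimal precision used for reporting."""
        return round(self.increase, 2)


def incorporation_increase(
    abundance_labeled: float,
    abundance_control: float,
    fragments: Sequence[FragmentSpec] = HB_FRAGMENTS,
    monomer: MonomerSpec = PHB,
    strain: str = "",
) -> IncorporationResult:
    """Convert a labelled/control abundance pair (percent) to mmol 13C per g.

    delta = (labelled - control)/100 is the net atom-fraction gain; each gram
    of polymer contains (mean fragment carbons)/M mol of quantified carbon
    positions, so the 13C gain is delta * n_C / M mol/g, reported in mmol/g.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    n_c = float(np.mean([f.n_carbons for f in fragments]))
    return IncorporationResult(
        strain, abundance_labeled, abundance_control,
        mean_fragment_carbons=n_c, monomer=monomer,
    )


def fold_ratio(a: IncorporationResult, b: IncorporationResult,
               *, reported_precision: bool = True) -> float:
    """Ratio of incorporation increases, a over b.

    By default the 2-decimal reported increases are compared, matching how
    fold changes are quoted from a results table; set
    ``reported_precision=False`` for full-precision internal values.
    """
    num = a.increase_reported if reported_precision else a.increase
    den = b.increase_reported if reported_precision else b.increase
    if den <= 0:
        raise ZeroDivisionError(
            f"reference strain {b.strain or '(unnamed)'} has non-positive increase"
        )
    return num / den


def estimate_enrichment(mids: Sequence[FragmentMID]) -> tuple[float, float | None]:
    """Mean and standard error of atom fractions over replicate spectra.

    With a single spectrum the SE is undefined and returned as None.
    """
    if not mids:
        raise ValueError("need at least one spectrum")
    fracs = np.array([atom_fraction(m) for m in mids])
    mean = float(fracs.mean())
    if fracs.size < 2:
        return mean, None
    se = float(fracs.std(ddof=1) / np.sqrt(fracs.size))
    return mean, se


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_mid_table(path: str | Path) -> pd.DataFrame:
    """Read a MID TSV: sample_id, strain, condition, fragment_label,
    n_carbons, M0..Mn (unused trailing channels may be empty)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "strain", "condition", "fragment_label", "n_carbons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def mids_from_table(df: pd.DataFrame) -> list[dict]:
    """Rows -> dicts with a FragmentMID each, keeping sample metadata."""
    out = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        abund = np.array(
            [float(row[f"M{i}"]) for i in range(n + 1)], dtype=float
        )
        out.append(
            {
                "sample_id": row["sample_id"],
                "strain": row["strain"],
                "condition": row["condition"],
                "mid": FragmentMID(FragmentSpec(str(row["fragment_label"]), n), abund),
            }
        )
    return out


def analyze_incorporation(
    mid_table: pd.DataFrame,
    control_condition: str = "12C",
    labeled_condition: str = "13C",
    monomer: MonomerSpec = PHB,
) -> pd.DataFrame:
    """Per-strain 13C abundances and incorporation increases from a MID table.

    For each strain, the mean 13C abundance (percent) is computed separately
    for the labelled and the control condition (averaging fragments, then
    sample replicates), and converted to an incorporation increase. Returns
    a frame indexed by strain with columns ``abundance_13C``,
    ``abundance_12C``, ``delta_atom_fraction``, ``increase_mmol_per_g``.
    """
    entries = mids_from_table(mid_table)
    rows = {}
    for strain in sorted({e["strain"] for e in entries}):
        per_cond = {}
        for cond in (labeled_condition, control_condition):
            sample_means = {}
            for e in entries:
                if e["strain"] == strain and e["condition"] == cond:
                    sample_means.setdefault(e["sample_id"], []).append(e["mid"])
            if not sample_means:
                raise ValueError(f"strain {strain!r}: no {cond!r} spectra")
            per_cond[cond] = float(
                np.mean([mean_abundance(m) for m in sample_means.values()])
            )
        frags = tuple(
            {e["mid"].fragment for e in entries if e["strain"] == strain}
        )
        res = incorporation_increase(
            per_cond[labeled_condition], per_cond[control_condition],
            fragments=frags or HB_FRAGMENTS, monomer=monomer, strain=strain,
        )
        rows[strain] = {
            "abundance_13C": res.abundance_labeled,
            "abundance_12C": res.abundance_control,
            "delta_atom_fraction": res.delta,
            "increase_mmol_per_g": res.increase,
            "increase_reported": res.increase_reported,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
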