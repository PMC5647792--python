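"""Formula-based lipid annotation.

Monoisotopic masses from a fixed most-abundant-isotope constant table,
adduct m/z for the three ion forms seen in plasma glycerophospholipid
work (M+H in positive mode; M−H and M−CH3 in negative mode), signed
ppm mass error, retention-time class windows for a CSH C18 gradient,
class-diagnostic fragment ions, and identification-confidence levels
(1 = authentic-standard MS/MS match, 2 = theoretical-fragment or
MS1+RT evidence, 3 = MS1 only).

A small built-in candidate list covers the lysophosphatidylcholines,
phosphatidylcholines, phosphatidic acids and phosphatidylinositols
typically reported differential in psoriasis plasma; user candidate
lists are plain TSV (name, class, formula, adducts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ChemFormula",
    "AdductRule",
    "LipidCandidate",
    "LipidAnnotation",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "match_features",
    "diagnostic_fragments",
    "assign_msi_level",
    "read_candidates",
    "ADDUCTS",
    "RT_WINDOWS",
    "BUILTIN_CANDIDATES",
]

# most-abundant-isotope masses, Da
ISOTOPE_MASS = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
}
PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858
CH3_MASS = ISOTOPE_MASS["C"] + 3 * ISOTOPE_MASS["H"]   # methyl radical, 15.023475

HILL_ORDER = ("C", "H", "N", "O", "P", "S")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemFormula:
    """Element → count map for a neutral molecular formula."""

    counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in HILL_ORDER:
            n = d.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __add__(self, other: "ChemFormula") -> "ChemFormula":
        d = self.as_dict()
        for el, n in other.as_dict().items():
            d[el] = d.get(el, 0) + n
        return ChemFormula(tuple(sorted(d.items())))


def parse_formula(text: str) -> ChemFormula:
    """Parse an element-count string such as ``"C24H50NO7P"``.

    Implicit count 1 is allowed; unknown elements, zero counts and
    trailing garbage raise with the offending position.
    """
    if not text or not text.strip():
        raise ValueError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"unparseable formula '{text}' at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPE_MASS:
            raise ValueError(f"unknown element '{el}' at position {pos} in '{text}'")
        n = int(num) if num else 1
        if n < 1:
            raise ValueError(f"count must be >= 1 for '{el}' at position {pos}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return ChemFormula(tuple(sorted(counts.items())))


def monoisotopic_mass(formula: ChemFormula | str) -> float:
    """Neutral monoisotopic mass in Da (most-abundant isotopes)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ISOTOPE_MASS[el] * n for el, n in formula.counts)


@dataclass(frozen=True)
class AdductRule:
    """Charge-1 ion form: m/z = neutral mass + shift."""

    name: str
    mode: str        # "positive" | "negative"
    shift: float     # Da


def _make_adducts(electron_convention: bool = False) -> dict[str, AdductRule]:
    # M-CH3: loss of a methyl radical by default; with the electron
    # convention the demethylated anion additionally gains an electron
    ch3_shift = -CH3_MASS + (ELECTRON_MASS if electron_convention else 0.0)
    return {
        "M+H": AdductRule("M+H", "positive", +PROTON_MASS),
        "M-H": AdductRule("M-H", "negative", -PROTON_MASS),
        "M-CH3": AdductRule("M-CH3", "negative", ch3_shift),
    }


ADDUCTS = _make_adducts()


def adduct_mz(neutral_mass: float, rule: AdductRule | str) -> float:
    """m/z of the charge-1 ion for a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if isinstance(rule, str):
        try:
            rule = ADDUCTS[rule]
        except KeyError:
            raise ValueError(f"unknown adduct '{rule}'") from None
    return neutral_mass + rule.shift


def neutral_from_mz(mz: float, rule: AdductRule | str) -> float:
    """Inverse of :func:`adduct_mz`."""
    if isinstance(rule, str):
        rule = ADDUCTS[rule]
    return mz - rule.shift


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


# retention-time windows (minutes) per lipid class on a CSH C18 gradient;
# user-overridable
RT_WINDOWS: dict[str, tuple[float, float]] = {
    "LysoPC": (0.7, 2.2),
    "PC": (6.7, 7.6),
    "PA": (5.6, 6.6),
    "PI": (4.5, 7.3),
}


@dataclass(frozen=True)
class LipidCandidate:
    """One database entry: name, class, neutral formula, allowed adducts."""

    name: str
    lipid_class: str
    formula: str
    adducts: tuple[str, ...]
    chains: tuple[tuple[int, int], ...] = ()   # (carbons, double bonds) per sn chain


# the differential plasma glycerophospholipids this pipeline targets
BUILTIN_CANDIDATES: tuple[LipidCandidate, ...] = (
    LipidCandidate("LysoPC(16:0)", "LysoPC", "C24H50NO7P", ("M+H", "M-CH3"), ((16, 0),)),
    LipidCandidate("LysoPC(17:0)", "LysoPC", "C25H52NO7P", ("M+H",), ((17, 0),)),
    LipidCandidate("LysoPC(18:0)", "LysoPC", "C26H54NO7P", ("M+H", "M-CH3"), ((18, 0),)),
    LipidCandidate("LysoPC(22:6)", "LysoPC", "C30H50NO7P", ("M+H",), ((22, 6),)),
    LipidCandidate("PC(16:0/18:1)", "PC", "C42H82NO8P", ("M-CH3",), ((16, 0), (18, 1))),
    LipidCandidate("PC(18:0/18:1)", "PC", "C44H86NO8P", ("M+H", "M-CH3"), ((18, 0), (18, 1))),
    LipidCandidate("PA(40:6)", "PA", "C43H73O8P", ("M-H",), ((40, 6),)),
    LipidCandidate("PA(38:4)", "PA", "C41H73O8P", ("M-H",), ((38, 4),)),
    LipidCandidate("PI(16:0/16:0)", "PI", "C41H79O13P", ("M-H",), ((16, 0), (16, 0))),
    LipidCandidate("PI(16:0/16:1)", "PI", "C41H77O13P", ("M-H",), ((16, 0), (16, 1))),
    LipidCandidate("PI(16:0/18:1)", "PI", "C43H81O13P", ("M-H",), ((16, 0), (18, 1))),
    LipidCandidate("PI(16:0/20:4)", "PI", "C45H79O13P", ("M-H",), ((16, 0), (20, 4))),
    LipidCandidate("PI(18:0/20:2)", "PI", "C47H87O13P", ("M-H",), ((18, 0), (20, 2))),
    LipidCandidate("PI(18:0/20:3)", "PI", "C47H85O13P", ("M-H",), ((18, 0), (20, 3))),
    LipidCandidate("PI(18:0/22:4)", "PI", "C49H87O13P", ("M-H",), ((18, 0), (22, 4))),
    LipidCandidate("PI(18:1/18:2)", "PI", "C45H81O13P", ("M-H",), ((18, 1), (18, 2))),
    LipidCandidate("PI(18:1/20:3)", "PI", "C47H83O13P", ("M-H",), ((18, 1), (20, 3))),
)


def read_candidates(path: str | Path) -> list[LipidCandidate]:
    """Read a candidate list TSV with columns name, class, formula, adducts
    (comma-separated)."""
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("name", "class", "formula", "adducts"):
        if col not in df.columns:
            raise ValueError(f"candidate list is missing column '{col}'")
    out = []
    for _, row in df.iterrows():
        out.append(
            LipidCandidate(
                name=str(row["name"]),
                lipid_class=str(row["class"]),
                formula=str(row["formula"]),
                adducts=tuple(a.strip() for a in str(row["adducts"]).split(",")),
            )
        )
    return out


@dataclass
class LipidAnnotation:
    """One feature↔candidate match with its evidence trail."""

    feature_id: str
    name: str
    lipid_class: str
    formula: str
    adduct: str
    neutral_mass: float
    theoretical_mz: float
    ppm_error: float
    rt_ok: bool | None          # None when the class has no RT window
    ms2_evidence: str = "none"  # standard_match | fragment_match | none
    msi_level: int = 3


def match_features(
    features: pd.DataFrame,
    candidates: list[LipidCandidate] | None = None,
    ms1_tol: float = 10.0,
    windows: dict[str, tuple[float, float]] | None = None,
) -> list[LipidAnnotation]:
    """Annotate features against candidate lipids at an MS1 ppm tolerance.

    ``features`` is indexed by feature id with columns ``mz``, ``rt``,
    ``ion_mode``.  A candidate is emitted iff some adduct valid in the
    feature's ion mode matches within ``ms1_tol`` ppm AND the feature's
    retention time falls in the class window; classes without a window
    pass the RT check with ``rt_ok=None``.  Matches are returned ranked
    by absolute ppm error within each feature.
    """
    if candidates is None:
        candidates = list(BUILTIN_CANDIDATES)
    if windows is None:
        windows = RT_WINDOWS
    annotations: list[LipidAnnotation] = []
    for fid, row in features.iterrows():
        mode = row["ion_mode"]
        hits: list[LipidAnnotation] = []
        for cand in candidates:
            neutral = monoisotopic_mass(cand.formula)
            window = windows.get(cand.lipid_class)
            for adduct_name in cand.adducts:
                rule = ADDUCTS.get(adduct_name)
                if rule is None or rule.mode != mode:
                    continue
                theo = adduct_mz(neutral, rule)
                err = ppm_error(float(row["mz"]), theo)
                if abs(err) > ms1_tol:
                    continue
                if window is not None:
                    rt_ok = window[0] <= float(row["rt"]) <= window[1]
                    if not rt_ok:
                        continue
                else:
                    rt_ok = None
                hits.append(
                    LipidAnnotation(
                        feature_id=str(fid),
                        name=cand.name,
                        lipid_class=cand.lipid_class,
                        formula=cand.formula,
                        adduct=adduct_name,
                        neutral_mass=neutral,
                        theoretical_mz=theo,
                        ppm_error=err,
                        rt_ok=rt_ok,
                    )
                )
        hits.sort(key=lambda a: abs(a.ppm_error))
        annotations.extend(hits)
    return annotations


def _acyl_anion_mz(carbons: int, double_bonds: int) -> float:
    """Fatty-acyl carboxylate anion [CcH(2c-1-2d)O2]⁻ m/z."""
    h = 2 * carbons - 1 - 2 * double_bonds
    mass = carbons * ISOTOPE_MASS["C"] + h * ISOTOPE_MASS["H"] + 2 * ISOTOPE_MASS["O"]
    return mass + ELECTRON_MASS


# phosphocholine head group C5H15NO4P+ (cation: minus one electron)
PHOSPHOCHOLINE_MZ = monoisotopic_mass("C5H15NO4P") - ELECTRON_MASS
# inositol phosphate head group after water loss, deprotonated: [C6H11O8P - H]-
INOSITOL_PHOSPHATE_MZ = monoisotopic_mass("C6H11O8P") - PROTON_MASS


def diagnostic_fragments(
    lipid_class: str,
    mode: str,
    chains: tuple[tuple[int, int], ...] = (),
    neutral_mass: float | None = None,
) -> list[float]:
    """Class-diagnostic product-ion m/z values.

    Positive-mode PC/LysoPC: the phosphocholine head at 184.0733.
    Negative-mode PC/LysoPC: the demethylated [M−CH3]⁻ ion (requires
    ``neutral_mass``).  Negative-mode PI: the dehydrated inositol
    phosphate at 241.0119 plus the fatty-acyl anions of its chains.
    Negative-mode PA: the fatty-acyl anions.
    """
    frags: list[float] = []
    if lipid_class in ("PC", "LysoPC"):
        if mode == "positive":
            frags.append(PHOSPHOCHOLINE_MZ)
        elif mode == "negative":
            if neutral_mass is not None:
                frags.append(adduct_mz(neutral_mass, "M-CH3"))
            frags.extend(_acyl_anion_mz(c, d) for c, d in chains)
        else:
            raise ValueError(f"unknown ion mode '{mode}'")
    elif lipid_class == "PI":
        if mode != "negative":
            raise ValueError("PI diagnostics are negative-mode only")
        frags.append(INOSITOL_PHOSPHATE_MZ)
        frags.extend(_acyl_anion_mz(c, d) for c, d in chains)
    elif lipid_class == "PA":
        if mode != "negative":
            raise ValueError("PA diagnostics are negative-mode only")
        frags.extend(_acyl_anion_mz(c, d) for c, d in chains)
    else:
        raise ValueError(f"unknown lipid class '{lipid_class}'")
    return frags


def assign_msi_level(annotation: LipidAnnotation, evidence: str) -> int:
    """Identification-confidence level from the available MS2 evidence.

    Level 1: MS/MS matches an authentic standard or curated spectrum.
    Level 2: theoretical-fragment MS/MS match, or MS1 match inside a
    class-consistent RT window.  Level 3: MS1 match only.
    """
    if evidence not in ("standard_match", "fragment_match", "none"):
        raise ValueError(f"unknown evidence token '{evidence}'")
    annotation.ms2_evidence = evidence
    if evidence == "standard_match":
        level = 1
    elif evidence == "fragment_match" or annotation.rt_ok is True:
        level = 2
    else:
        level = 3
    annotation.msi_level = level
    return level
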