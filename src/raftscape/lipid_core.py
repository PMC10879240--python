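"""Lipid profile data model, derived indexes and cohort CSV I/O.

Profiles come in two flavours mirroring the two analytical tables of a
raft lipidomics experiment: fatty-acid composition (mol% of total fatty
acids plus dimethylacetals, from gas chromatography of FAMEs/DMAs) and
lipid-class composition (% of total lipid, from HPTLC densitometry).
On top of these, the module computes every total, ratio and index used
in the downstream statistics: series totals, total LCPUFA and DMAs, the
saturates-to-unsaturates ratio, unsaturation and peroxidability indexes,
the cholesterol-to-sterol-ester ratio and the anionic-to-zwitterionic
phospholipid ratio.

Conventions
-----------
* Unsaturation index (UIx) = sum over species of mol% x number of double
  bonds; dimethylacetals are excluded.
* Peroxidability index (PIx) = 0.025 x monoenes + 1 x dienes + 2 x trienes
  + 4 x tetraenes + 6 x pentaenes + 8 x hexaenes (percent units), the
  standard lipidomics weighting; DMAs excluded.
* Sat/Unsat excludes DMAs from both numerator and denominator: DMAs proxy
  plasmalogen ether chains and are analysed as their own family.
* Anionic = PG + PI + PS; zwitterionic = PC + PE (SM is counted with the
  sphingolipids, not as a zwitterionic phospholipid here).
* Compositional closure: a profile must sum to 100 within +-1 (warning)
  and within +-5 (hard error) on read.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FattyAcidSpecies",
    "FattyAcidProfile",
    "LipidClassProfile",
    "DerivedIndexSet",
    "SubjectRecord",
    "SpeciesParseError",
    "ClosureError",
    "parse_species",
    "compute_totals",
    "unsaturation_index",
    "peroxidability_index",
    "class_ratios",
    "derive_indexes",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "indexes_to_json",
    "CLASS_TOKENS",
    "ANIONIC_CLASSES",
    "ZWITTERIONIC_CLASSES",
    "SPHINGOLIPID_CLASSES",
]

#: canonical lipid-class column tokens
CLASS_TOKENS = ("PC", "PE", "PS", "PI", "PG", "SM", "SULF", "OTHER_SL", "CHO", "SE")
ANIONIC_CLASSES = ("PG", "PI", "PS")
ZWITTERIONIC_CLASSES = ("PC", "PE")
SPHINGOLIPID_CLASSES = ("SM", "SULF", "OTHER_SL")

#: peroxidability weights per number of double bonds (1..6)
_PIX_WEIGHTS = {1: 0.025, 2: 1.0, 3: 2.0, 4: 4.0, 5: 6.0, 6: 8.0}

#: closure tolerances for percentage tables
CLOSURE_WARN = 1.0
CLOSURE_ERROR = 5.0


class SpeciesParseError(ValueError):
    """A fatty-acid name token could not be parsed."""


class ClosureError(ValueError):
    """A percentage profile fails the sum-to-100 closure check."""


_SPECIES_RE = re.compile(
    r"^(?P<carbons>\d{1,2}):(?P<db>\d{1,2})(?:n-(?P<series>\d{1,2}))?"
    r"(?P<dma>\s+DMA)?$"
)


@dataclass(frozen=True)
class FattyAcidSpecies:
    """One fatty acid or dimethylacetal, parsed from its shorthand name.

    ``series`` is one of ``saturate``, ``n-9``, ``n-7``, ``n-6``, ``n-3``
    or ``DMA``; a DMA keeps the double-bond count of the chain it derives
    from (``18:1n-9 DMA`` has one double bond).
    """

    name: str
    carbons: int
    double_bonds: int
    series: str
    is_dma: bool = False

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise SpeciesParseError(f"non-positive carbon number in {self.name!r}")
        if self.double_bonds < 0:
            raise SpeciesParseError(f"negative double bonds in {self.name!r}")
        if not self.is_dma and (self.double_bonds == 0) != (self.series == "saturate"):
            raise SpeciesParseError(
                f"{self.name!r}: zero double bonds and series {self.series!r} disagree"
            )


def parse_species(name: str) -> FattyAcidSpecies:
    """Parse a shorthand token like ``"18:0"``, ``"20:4n-6"`` or ``"16:0 DMA"``.

    The grammar is ``C:D``, ``C:Dn-S`` or either followed by `` DMA``.
    Raises :class:`SpeciesParseError` naming the offending token.
    """
    m = _SPECIES_RE.match(name.strip())
    if m is None:
        raise SpeciesParseError(f"cannot parse fatty-acid token {name!r}")
    carbons = int(m.group("carbons"))
    db = int(m.group("db"))
    is_dma = m.group("dma") is not None
    raw_series = m.group("series")
    if is_dma:
        series = "DMA"
    elif db == 0:
        if raw_series is not None:
            raise SpeciesParseError(f"{name!r}: saturated chain cannot carry a series")
        series = "saturate"
    else:
        if raw_series is None:
            raise SpeciesParseError(f"{name!r}: unsaturated chain needs an n-series")
        series = f"n-{raw_series}"
        if series not in ("n-9", "n-7", "n-6", "n-3"):
            raise SpeciesParseError(f"{name!r}: unknown series {series!r}")
    if db == 0 and raw_series is not None:
        raise SpeciesParseError(f"{name!r}: saturated chain cannot carry a series")
    canonical = f"{carbons}:{db}"
    if raw_series is not None:
        canonical += f"n-{raw_series}"
    if is_dma:
        canonical += " DMA"
    return FattyAcidSpecies(canonical, carbons, db, series, is_dma)


def _check_closure(total: float, label: str, *, strict: bool = True) -> None:
    dev = abs(total - 100.0)
    if dev > CLOSURE_ERROR and strict:
        raise ClosureError(f"{label}: percentages sum to {total:.3f}, outside 100+-{CLOSURE_ERROR}")
    if dev > CLOSURE_WARN:
        warnings.warn(
            f"{label}: percentages sum to {total:.3f}, outside 100+-{CLOSURE_WARN}",
            stacklevel=3,
        )


@dataclass
class FattyAcidProfile:
    """Per-subject fatty-acid composition in mol% of total (FAME + DMA)."""

    subject_id: str
    values: dict[str, float]
    _species: dict[str, FattyAcidSpecies] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"{self.subject_id}: empty fatty-acid profile")
        self._species = {tok: parse_species(tok) for tok in self.values}
        if any(v < 0 for v in self.values.values()):
            raise ValueError(f"{self.subject_id}: negative fatty-acid percentage")
        _check_closure(self.total, f"fatty acids of {self.subject_id}")

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))

    def species(self) -> list[FattyAcidSpecies]:
        return [self._species[tok] for tok in self.values]

    def renormalized(self) -> "FattyAcidProfile":
        """Return a copy rescaled to sum exactly to 100."""
        s = self.total
        return FattyAcidProfile(self.subject_id, {k: 100.0 * v / s for k, v in self.values.items()})


@dataclass
class LipidClassProfile:
    """Per-subject lipid-class composition in % of total lipid."""

    subject_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"{self.subject_id}: empty lipid-class profile")
        if any(v < 0 for v in self.values.values()):
            raise ValueError(f"{self.subject_id}: negative lipid-class percentage")
        _check_closure(self.total, f"lipid classes of {self.subject_id}")

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))

    def get(self, token: str, default: float = 0.0) -> float:
        return float(self.values.get(token, default))

    def renormalized(self) -> "LipidClassProfile":
        s = self.total
        return LipidClassProfile(self.subject_id, {k: 100.0 * v / s for k, v in self.values.items()})


@dataclass
class DerivedIndexSet:
    """Every derived total/ratio/index analysed downstream.

    Ratio fields are NaN (never an exception) when their denominator is
    zero; ``undefined`` lists which fields were flagged that way.
    """

    total_saturates: float = 0.0
    total_mufa: float = 0.0
    total_n9: float = 0.0
    total_n7: float = 0.0
    total_n6: float = 0.0
    total_n3: float = 0.0
    total_lcpufa: float = 0.0
    total_n6_lcpufa: float = 0.0
    total_n3_lcpufa: float = 0.0
    total_dma: float = 0.0
    total_unsaturates: float = 0.0
    sat_unsat_ratio: float = float("nan")
    n3_n6_ratio: float = float("nan")
    uix: float = 0.0
    pix: float = 0.0
    cho_se_ratio: float = float("nan")
    anionic_zwitterionic_ratio: float = float("nan")
    total_sphingolipids: float = 0.0
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d.pop("undefined")
        return d


def _safe_ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def compute_totals(fa: FattyAcidProfile) -> DerivedIndexSet:
    """Series totals, MUFA/LCPUFA/DMA totals and the Sat/Unsat ratio.

    LCPUFA are species with >= 20 carbons and >= 2 double bonds.  DMAs are
    totalled separately and excluded from the saturate/unsaturate sums.
    """
    out = DerivedIndexSet()
    undefined: list[str] = []
    for sp in fa.species():
        v = fa.values[sp.name]
        if sp.is_dma:
            out.total_dma += v
            continue
        if sp.double_bonds == 0:
            out.total_saturates += v
        else:
            out.total_unsaturates += v
        if sp.double_bonds == 1:
            out.total_mufa += v
        if sp.series == "n-9":
            out.total_n9 += v
        elif sp.series == "n-7":
            out.total_n7 += v
        elif sp.series == "n-6":
            out.total_n6 += v
        elif sp.series == "n-3":
            out.total_n3 += v
        if sp.carbons >= 20 and sp.double_bonds >= 2:
            out.total_lcpufa += v
            if sp.series == "n-6":
                out.total_n6_lcpufa += v
            elif sp.series == "n-3":
                out.total_n3_lcpufa += v
    out.sat_unsat_ratio = _safe_ratio(
        out.total_saturates, out.total_unsaturates, "sat_unsat_ratio", undefined
    )
    out.n3_n6_ratio = _safe_ratio(out.total_n3, out.total_n6, "n3_n6_ratio", undefined)
    out.uix = unsaturation_index(fa)
    out.pix = peroxidability_index(fa)
    out.undefined = tuple(undefined)
    return out


def unsaturation_index(fa: FattyAcidProfile) -> float:
    """UIx = sum of mol% x double bonds over non-DMA species."""
    return float(
        sum(fa.values[sp.name] * sp.double_bonds for sp in fa.species() if not sp.is_dma)
    )


def peroxidability_index(fa: FattyAcidProfile) -> float:
    """PIx with the conventional 0.025/1/2/4/6/8 weights, DMAs excluded."""
    total = 0.0
    for sp in fa.species():
        if sp.is_dma or sp.double_bonds == 0:
            continue
        w = _PIX_WEIGHTS.get(sp.double_bonds)
        if w is None:
            raise ValueError(f"no peroxidability weight for {sp.double_bonds} double bonds")
        total += fa.values[sp.name] * w
    return float(total)


def class_ratios(lc: LipidClassProfile) -> DerivedIndexSet:
    """CHO/SE, anionic/zwitterionic ratio and total sphingolipids."""
    out = DerivedIndexSet()
    undefined: list[str] = []
    out.cho_se_ratio = _safe_ratio(lc.get("CHO"), lc.get("SE"), "cho_se_ratio", undefined)
    anionic = sum(lc.get(t) for t in ANIONIC_CLASSES)
    zwitter = sum(lc.get(t) for t in ZWITTERIONIC_CLASSES)
    out.anionic_zwitterionic_ratio = _safe_ratio(
        anionic, zwitter, "anionic_zwitterionic_ratio", undefined
    )
    out.total_sphingolipids = float(sum(lc.get(t) for t in SPHINGOLIPID_CLASSES))
    out.undefined = tuple(undefined)
    return out


def derive_indexes(fa: FattyAcidProfile, lc: LipidClassProfile) -> DerivedIndexSet:
    """Merge fatty-acid totals/indexes with lipid-class ratios."""
    out = compute_totals(fa)
    cls = class_ratios(lc)
    out.cho_se_ratio = cls.cho_se_ratio
    out.anionic_zwitterionic_ratio = cls.anionic_zwitterionic_ratio
    out.total_sphingolipids = cls.total_sphingolipids
    out.undefined = tuple(list(out.undefined) + list(cls.undefined))
    return out


@dataclass
class SubjectRecord:
    """One subject: group label, demographics and both lipid tables."""

    subject_id: str
    group: str
    fatty_acids: FattyAcidProfile
    lipid_classes: LipidClassProfile
    sex: str = "U"
    age: float = float("nan")
    pmd: float = float("nan")

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError(f"{self.subject_id}: missing group label")
        for prof in (self.fatty_acids, self.lipid_classes):
            if prof.subject_id != self.subject_id:
                raise ValueError(
                    f"profile subject_id {prof.subject_id!r} != record {self.subject_id!r}"
                )

    def indexes(self) -> DerivedIndexSet:
        return derive_indexes(self.fatty_acids, self.lipid_classes)


_META_COLUMNS = ("subject_id", "group", "sex", "age", "pmd")


def cohort_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into the on-disk table: metadata, then FA, then class columns."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    fa_cols = list(records[0].fatty_acids.values)
    lc_cols = list(records[0].lipid_classes.values)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "group": r.group,
            "sex": r.sex,
            "age": r.age,
            "pmd": r.pmd,
        }
        row.update({c: r.fatty_acids.values[c] for c in fa_cols})
        row.update({c: r.lipid_classes.values[c] for c in lc_cols})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_META_COLUMNS) + fa_cols + lc_cols)


def write_cohort(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write a cohort as UTF-8 comma-separated text, one row per subject."""
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV back into records.

    Columns are split into fatty-acid and lipid-class tables by token
    grammar: anything :func:`parse_species` accepts is a fatty acid,
    anything in :data:`CLASS_TOKENS` is a lipid class; other non-metadata
    columns raise the underlying :class:`SpeciesParseError`.
    """
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise ValueError(f"{path}: missing required 'group' column")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'subject_id' column")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate subject_id values {dupes}")
    fa_cols, lc_cols = [], []
    for col in df.columns:
        if col in _META_COLUMNS:
            continue
        if col in CLASS_TOKENS:
            lc_cols.append(col)
        else:
            parse_species(col)  # raises with the offending token
            fa_cols.append(col)
    records = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        fa = FattyAcidProfile(sid, {c: float(row[c]) for c in fa_cols})
        lc = LipidClassProfile(sid, {c: float(row[c]) for c in lc_cols})
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=str(row["group"]),
                sex=str(row.get("sex", "U")),
                age=float(row.get("age", np.nan)),
                pmd=float(row.get("pmd", np.nan)),
                fatty_acids=fa,
                lipid_classes=lc,
            )
        )
    return records


def indexes_to_json(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Export per-subject derived indexes as a JSON object keyed by subject."""
    payload = {r.subject_id: r.indexes().as_dict() for r in records}
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def index_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Per-subject derived indexes as a DataFrame (subject_id index, group column)."""
    records = list(records)
    df = pd.DataFrame([r.indexes().as_dict() for r in records])
    df.insert(0, "group", [r.group for r in records])
    df.index = pd.Index([r.subject_id for r in records], name="subject_id")
    return df
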