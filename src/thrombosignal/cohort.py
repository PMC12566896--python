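"""Steroid-cohort selection by SMARTS substructure match.

The steroid pharmacophore is the tetracyclic 6-6-6-5 all-carbon gonane
skeleton.  The screening pattern uses element-only atoms (``[#6]``) and
any-order bonds (``~``), so saturated, unsaturated and aromatic-ring
steroids (e.g. estrogens, whose A ring is aromatic) all match, while no
stereo, charge or hydrogen constraints are imposed::

    [#6]~1~[#6]~[#6]~2~[#6]~[#6]~[#6]~3~[#6](~[#6]~[#6]~[#6]~4~[#6]~
    [#6]~[#6]~[#6]~[#6]~3~4)~[#6]~2~[#6]~1

Drug structures come from a local name->SMILES dictionary (TSV); a
pluggable resolver can replace it with a live lookup.  Names that denote a
drug class or extract rather than a single structure (e.g. ``STEROIDS``)
are handled by an allowlist that force-includes them without a SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from thrombosignal.io import normalize_name

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "STEROID_SCAFFOLD_SMARTS",
    "InvalidSmilesError",
    "compile_pattern",
    "matches_scaffold",
    "CohortResult",
    "build_cohort",
    "market_filter",
    "classify",
    "load_smiles_dictionary",
    "load_class_map",
    "load_allowlist",
]

#: any-carbon / any-bond SMARTS for the fused 6-6-6-5 steroid skeleton
STEROID_SCAFFOLD_SMARTS = (
    "[#6]~1~[#6]~[#6]~2~[#6]~[#6]~[#6]~3~[#6](~[#6]~[#6]~[#6]~4~[#6]~[#6]~"
    "[#6]~[#6]~[#6]~3~4)~[#6]~2~[#6]~1"
)


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def compile_pattern(smarts: str = STEROID_SCAFFOLD_SMARTS) -> Chem.Mol:
    """Compile a SMARTS pattern, validating it against testosterone."""
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise ValueError(f"SMARTS pattern does not compile: {smarts!r}")
    return pattern


def matches_scaffold(smiles: str, pattern: Chem.Mol | None = None) -> bool:
    """True iff the molecule contains the scaffold as a subgraph.

    Raises :class:`InvalidSmilesError` for unparseable SMILES — an invalid
    structure is a distinct outcome, never silently ``False``.
    """
    if pattern is None:
        pattern = compile_pattern()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol.HasSubstructMatch(pattern)


@dataclass
class CohortResult:
    """Partition of the input names produced by :func:`build_cohort`."""

    cohort: set[str] = field(default_factory=set)
    unmapped: set[str] = field(default_factory=set)
    invalid: set[str] = field(default_factory=set)
    nonmatching: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = ([(n, True, "matched") for n in sorted(self.cohort)]
                + [(n, False, "no-structure") for n in sorted(self.unmapped)]
                + [(n, False, "invalid-structure")
                   for n in sorted(self.invalid)]
                + [(n, False, "non-steroid")
                   for n in sorted(self.nonmatching)])
        return pd.DataFrame(rows, columns=["drug_name", "matched", "source"])


def build_cohort(drug_names: Iterable[str],
                 smiles_dict: Mapping[str, str],
                 pattern: Chem.Mol | None = None,
                 allowlist: Iterable[str] | None = None) -> CohortResult:
    """Partition drug names into cohort / unmapped / invalid / non-matching.

    ``allowlist`` names are force-included in the cohort even without a
    structure.  The four sets are disjoint and cover the input.
    """
    if not smiles_dict:
        raise ValueError("empty SMILES dictionary")
    if pattern is None:
        pattern = compile_pattern()
    smiles_dict = {normalize_name(k): v for k, v in smiles_dict.items()}
    allowed = {normalize_name(n) for n in (allowlist or [])}
    result = CohortResult()
    for raw in drug_names:
        name = normalize_name(raw)
        if name in allowed:
            result.cohort.add(name)
            continue
        if name not in smiles_dict:
            result.unmapped.add(name)
            continue
        try:
            hit = matches_scaffold(smiles_dict[name], pattern)
        except InvalidSmilesError:
            result.invalid.add(name)
            continue
        (result.cohort if hit else result.nonmatching).add(name)
    return result


def market_filter(ther: pd.DataFrame, cutoff_year: int = 2024) -> set[str]:
    """Drugs with at least one therapy start in ``cutoff_year`` or later.

    A recent first administration indicates the drug is still in clinical
    use.  Dateless records are ignored (their count is logged via the
    return's complement being unaffected).
    """
    if "start_date" not in ther.columns:
        return set()
    years = pd.to_numeric(ther["start_date"].astype(str).str.strip().str[:4],
                          errors="coerce")
    recent = ther.loc[years >= cutoff_year, "drug_name"]
    return set(recent.unique())


def classify(drug_name: str, class_map: Mapping[str, str]) -> str:
    """Class label for a drug; ``"unclassified"`` for unknown names."""
    return class_map.get(normalize_name(drug_name), "unclassified")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # leading '#' comment lines are stripped by hand: SMILES legitimately
    # contain '#' (triple bonds), so pandas' comment= would truncate them
    import io as _io

    text = Path(path).read_text()
    body = "\n".join(line for line in text.splitlines()
                     if not line.lstrip().startswith("#"))
    return pd.read_csv(_io.StringIO(body), sep="\t", dtype=str)


def load_smiles_dictionary(path: str | Path) -> dict[str, str]:
    """drug_name -> SMILES map from a TSV with those two columns."""
    df = _read_tsv(path)
    for col in ("drug_name", "smiles"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    return {normalize_name(r["drug_name"]): str(r["smiles"])
            for _, r in df.iterrows()}


def load_class_map(path: str | Path) -> dict[str, str]:
    """drug_name -> class label map from a TSV."""
    df = _read_tsv(path)
    for col in ("drug_name", "class"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    return {normalize_name(r["drug_name"]): str(r["class"]).strip()
            for _, r in df.iterrows()}


def load_allowlist(path: str | Path) -> set[str]:
    df = _read_tsv(path)
    if "drug_name" not in df.columns:
        raise ValueError(f"{Path(path).name}: missing column 'drug_name'")
    return {normalize_name(n) for n in df["drug_name"]}


def _packaged(name: str) -> Path:
    ref = resources.files("thrombosignal.data") / name
    with resources.as_file(ref) as path:
        return path


def default_class_map() -> dict[str, str]:
    """The packaged curated steroid class map (18 classes)."""
    return load_class_map(_packaged("steroid_classes.tsv"))


def default_allowlist() -> set[str]:
    return load_allowlist(_packaged("steroid_allowlist.tsv"))


def scaffold_fixture() -> pd.DataFrame:
    """The packaged 20-molecule hand-labelled steroid/non-steroid fixture."""
    df = _read_tsv(_packaged("steroid_smiles.tsv"))
    df["is_steroid"] = df["is_steroid"].astype(int).astype(bool)
    return df
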