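"""SMQ-scoped preferred-term sets for thrombosis events.

MedDRA groups preferred terms (PTs) into Standardised MedDRA Queries; the
three narrow-scope queries of interest here cover arterial, venous, and
unspecified-or-mixed-vessel embolism/thrombosis.  MedDRA itself is licensed
and is not bundled: term sets are flat TSV files with a ``pt`` column and a
``scope`` column drawn from {arterial, venous, mixed}.

A curated 52-term thrombosis set ships as package data
(``data/thrombosis_terms.tsv``); its arterial/venous/mixed scope labels are the
package's own SMQ-based assignment and are user-overridable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

SCOPES = frozenset({"arterial", "venous", "mixed"})


def normalize_pt(pt: str) -> str:
    """Case-insensitive, whitespace-collapsed preferred-term key."""
    return _WS.sub(" ", str(pt).strip()).upper()


@dataclass(frozen=True)
class SmqTermSet:
    """A named set of preferred terms, each tagged with a vessel scope."""

    name: str
    scopes: dict[str, str] = field(default_factory=dict)  # pt key -> scope

    def __post_init__(self):
        bad = set(self.scopes.values()) - SCOPES
        if bad:
            raise ValueError(f"unknown scope label(s): {sorted(bad)}")

    @property
    def pts(self) -> set[str]:
        return set(self.scopes)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.scopes

    def __len__(self) -> int:
        return len(self.scopes)

    def scope(self, pt: str) -> str:
        return self.scopes[normalize_pt(pt)]

    def by_scope(self, scope: str) -> set[str]:
        if scope not in SCOPES:
            raise ValueError(f"unknown scope {scope!r}")
        return {pt for pt, s in self.scopes.items() if s == scope}


def load_term_set(path: str | Path, name: str | None = None) -> SmqTermSet:
    """Load a term-set TSV with ``pt`` and ``scope`` columns.

    Duplicate PTs with conflicting scopes, and scope strings outside the
    closed set, are hard errors.  An empty file yields an empty set with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("pt", "scope"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    scopes: dict[str, str] = {}
    for _, row in df.iterrows():
        pt = normalize_pt(row["pt"])
        scope = str(row["scope"]).strip().lower()
        if scope not in SCOPES:
            raise ValueError(
                f"{path.name}: unknown scope {scope!r} for PT {pt!r}")
        if pt in scopes and scopes[pt] != scope:
            raise ValueError(
                f"{path.name}: PT {pt!r} listed with conflicting scopes "
                f"{scopes[pt]!r} and {scope!r}")
        scopes[pt] = scope
    if not scopes:
        logger.warning("%s: empty term set", path.name)
    return SmqTermSet(name or path.stem, scopes)


def is_thrombosis_event(pt: str, term_set: SmqTermSet) -> bool:
    """Case-insensitive, whitespace-normalized membership test."""
    return pt in term_set


def default_term_set() -> SmqTermSet:
    """The packaged 52-term thrombosis set with curated scope labels."""
    ref = resources.files("thrombosignal.data") / "thrombosis_terms.tsv"
    with resources.as_file(ref) as path:
        return load_term_set(path, name="thrombosis-smq-narrow")
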