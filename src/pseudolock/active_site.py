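"""Catalytic-site integrity calling for PPM-family phosphatase domains.

PPM (PP2C-type) Ser/Thr phosphatases need at least two divalent metal
ions, M1 and M2, held by a constellation of conserved aspartates (plus a
glutamate and backbone contacts) in the active site.  A sequence whose
aligned residues at the required M1 and M2 coordinating positions all
match the allowed residue sets is called catalytically *active*; any
required mismatch (including a deletion) makes it a *pseudo* enzyme
candidate.  M3 positions are reported but never affect the call, since
only M1+M2 are universally required for catalysis.

A cysteine observed at an M2-role position raises ``m2_zinc_flag``:
substitution of an M2 aspartate by cysteine converts the site into a
structural zinc-binding constellation — the signature by which human
PHLPP2 (C799/D820/D822/D1024) was recognized as a zinc protein rather
than a phosphatase.

Positions are numbered on an ungapped reference sequence (PPM1A by
convention) and mapped through the alignment, so the engine is agnostic
to any particular numbering scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, NotFoundError

__all__ = [
    "SitePosition",
    "CatalyticSiteModel",
    "ActiveSiteCall",
    "map_reference_positions",
    "call_active_site",
    "conservation_profile",
    "activity_character",
    "load_default_model",
]

GAP_CHARS = frozenset("-.")
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SitePosition:
    role: str  # M1 | M2 | M3
    position: int  # 1-based residue number on the ungapped reference
    allowed: frozenset[str]
    required: bool

    def __post_init__(self) -> None:
        if self.role not in ("M1", "M2", "M3"):
            raise InvalidArgumentError(f"unknown site role {self.role!r}")
        if not self.allowed:
            raise InvalidArgumentError("allowed residue set must be nonempty")
        if self.position < 1:
            raise InvalidArgumentError("positions are 1-based")


@dataclass(frozen=True)
class CatalyticSiteModel:
    """Metal-coordination site model anchored on a reference sequence."""

    reference_id: str
    sites: tuple[SitePosition, ...]

    def __post_init__(self) -> None:
        pos = [s.position for s in self.sites]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise InvalidArgumentError("site positions must be strictly increasing")
        roles_required = {s.role for s in self.sites if s.required}
        if "M1" not in roles_required or "M2" not in roles_required:
            raise InvalidArgumentError(
                "model needs at least one required M1 and one required M2 position"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "CatalyticSiteModel":
        sites = tuple(
            SitePosition(
                role=s["role"],
                position=int(s["position"]),
                allowed=frozenset(s["allowed"]),
                required=bool(s["required"]),
            )
            for s in d["sites"]
        )
        return cls(reference_id=d["reference_id"], sites=sites)

    @classmethod
    def from_json(cls, path) -> "CatalyticSiteModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "sites": [
                {
                    "role": s.role,
                    "position": s.position,
                    "allowed": sorted(s.allowed),
                    "required": s.required,
                }
                for s in self.sites
            ],
        }


@dataclass(frozen=True)
class ActiveSiteCall:
    sequence_id: str
    residues: tuple[tuple[str, int, str, bool], ...]  # (role, position, residue, matched)
    classification: str  # active | pseudo | ambiguous
    m2_zinc_flag: bool


def _as_rows(alignment) -> list[tuple[str, str]]:
    """Normalize a Bio.Align.MultipleSeqAlignment or id->sequence mapping."""
    if hasattr(alignment, "items"):
        rows = [(str(k), str(v)) for k, v in alignment.items()]
    else:
        rows = [(rec.id, str(rec.seq)) for rec in alignment]
    if not rows:
        raise InvalidArgumentError("empty alignment")
    width = len(rows[0][1])
    if any(len(s) != width for _, s in rows):
        raise InvalidArgumentError("alignment rows have unequal lengths")
    return rows


def map_reference_positions(
    alignment, model: CatalyticSiteModel
) -> dict[int, int]:
    """Map model residue numbers to 1-based alignment columns.

    The k-th non-gap character of the reference row occupies reference
    position k; the returned map gives its alignment column.
    """
    rows = dict(_as_rows(alignment))
    if model.reference_id not in rows:
        raise NotFoundError(f"reference {model.reference_id!r} not in alignment")
    ref = rows[model.reference_id]
    wanted = {s.position for s in model.sites}
    ungapped_len = sum(1 for c in ref if c not in GAP_CHARS)
    beyond = [p for p in wanted if p > ungapped_len]
    if beyond:
        raise InvalidArgumentError(
            f"model positions {sorted(beyond)} beyond reference length {ungapped_len}"
        )
    out: dict[int, int] = {}
    k = 0
    for col, char in enumerate(ref, start=1):
        if char in GAP_CHARS:
            continue
        k += 1
        if k in wanted:
            out[k] = col
    return out


def call_active_site(
    alignment, model: CatalyticSiteModel
) -> list[ActiveSiteCall]:
    """One integrity call per aligned sequence.

    A gap in a non-reference row at a required position counts as a
    mismatch (a deleted coordinating residue cannot bind metal).
    """
    rows = _as_rows(alignment)
    colmap = map_reference_positions(alignment, model)
    calls: list[ActiveSiteCall] = []
    for seq_id, seq in rows:
        residues = []
        ok_required = True
        any_unmapped = False
        zinc = False
        for site in model.sites:
            col = colmap.get(site.position)
            if col is None:
                any_unmapped = True
                residues.append((site.role, site.position, "?", False))
                continue
            res = seq[col - 1].upper()
            matched = res in site.allowed and res not in GAP_CHARS
            residues.append((site.role, site.position, res, matched))
            if site.required and not matched and site.role in ("M1", "M2"):
                ok_required = False
            if site.role == "M2" and res == "C":
                zinc = True
        if any_unmapped:
            classification = "ambiguous"
        elif ok_required:
            classification = "active"
        else:
            classification = "pseudo"
        calls.append(ActiveSiteCall(seq_id, tuple(residues), classification, zinc))
    return calls


def conservation_profile(
    alignment, columns: Sequence[int]
) -> tuple[pd.DataFrame, pd.Series]:
    """Residue frequencies and information content for selected columns.

    Frequencies are computed over non-gap characters only; an all-gap
    column is reported as undefined (NaN), not an error.  Information
    content is ``log2(20) - H`` bits, where H is the Shannon entropy of
    the column's residue distribution.
    """
    rows = _as_rows(alignment)
    width = len(rows[0][1])
    bad = [c for c in columns if not 1 <= c <= width]
    if bad:
        raise InvalidArgumentError(f"columns {bad} outside alignment width {width}")
    freq = pd.DataFrame(
        np.nan, index=list(AMINO_ACIDS), columns=list(columns), dtype=float
    )
    ic = pd.Series(np.nan, index=list(columns), dtype=float)
    for col in columns:
        chars = [s[col - 1].upper() for _, s in rows]
        chars = [c for c in chars if c not in GAP_CHARS]
        if not chars:
            continue  # undefined
        counts = pd.Series(chars).value_counts()
        counts = counts.reindex(list(AMINO_ACIDS), fill_value=0).astype(float)
        p = counts / counts.sum()
        freq[col] = p
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic[col] = np.log2(20.0) - entropy
    return freq, ic


def activity_character(calls: Iterable[ActiveSiteCall]) -> dict[str, int | None]:
    """Convert integrity calls into a binary tip character for Dollo mapping.

    active -> 1, pseudo -> 0, ambiguous -> missing; feeding this into
    ``infer_dollo`` maps active-site loss events on a phylogeny.
    """
    mapping = {"active": 1, "pseudo": 0, "ambiguous": None}
    return {c.sequence_id: mapping[c.classification] for c in calls}


def load_default_model() -> CatalyticSiteModel:
    """Shipped PPM1A-numbered site model.

    The residue numbers are an approximate transcription of the PPM1A
    metal-coordination constellation commonly cited in the structural
    literature; they are provided as a convenience default and should be
    replaced by the user's own model file when exact numbering matters.
    """
    ref = resources.files("pseudolock").joinpath("data/ppm1a_sites.json")
    with ref.open() as fh:
        return CatalyticSiteModel.from_dict(json.load(fh))
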