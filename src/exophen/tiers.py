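"""Tier-1 / Tier-2 consequence classification.

Tier-1 marks predicted high-impact changes: for SNVs a stop gain/loss, start
loss or splice-site change; for INDELs a frameshift or splice-site change.
Tier-2 marks missense SNVs with in-silico support (SIFT or PolyPhen calls the
change damaging) and in-frame codon-changing INDELs.  Everything else —
synonymous, unsupported missense, other — is non-reportable and dropped.

Splice-site membership comes from the annotated consequence; transcript
models are not re-derived.  A variant annotated as both splice-site and
missense would arrive as ``splice_site`` and take the higher tier.
"""
from __future__ import annotations

from typing import Iterable

from .types import INDEL, SNV, TieredVariant, VariantCall

__all__ = ["is_damaging", "classify", "classify_all"]

_TIER1_SNV = frozenset({"stop_gained", "stop_lost", "start_lost", "splice_site"})
_TIER1_INDEL = frozenset({"frameshift", "splice_site"})
_TIER2_INDEL = frozenset({"inframe_codon_change", "codon_insertion_deletion"})
_SNV_ONLY = frozenset({"stop_gained", "stop_lost", "start_lost", "missense"})
_INDEL_ONLY = frozenset({"frameshift", "inframe_codon_change",
                         "codon_insertion_deletion"})


def is_damaging(v: VariantCall) -> bool:
    """In-silico support for a missense change: either predictor suffices."""
    if v.consequence != "missense":
        raise ValueError("is_damaging applies to missense variants only")
    return v.sift == "damaging" or v.polyphen == "damaging"


def _check_consistency(v: VariantCall) -> None:
    if v.vclass == SNV and v.consequence in _INDEL_ONLY:
        raise ValueError(
            f"SNV with INDEL-only consequence {v.consequence} at {v.chrom}:{v.pos}")
    if v.vclass == INDEL and v.consequence in _SNV_ONLY:
        raise ValueError(
            f"INDEL with SNV-only consequence {v.consequence} at {v.chrom}:{v.pos}")


def classify(v: VariantCall) -> TieredVariant | None:
    """Assign a tier, or ``None`` for a non-reportable consequence."""
    _check_consistency(v)
    if v.vclass == SNV:
        if v.consequence in _TIER1_SNV:
            return TieredVariant(variant=v, tier=1, tier_basis=v.consequence)
        if v.consequence == "missense" and is_damaging(v):
            return TieredVariant(variant=v, tier=2, tier_basis="missense")
        return None
    if v.consequence in _TIER1_INDEL:
        return TieredVariant(variant=v, tier=1, tier_basis=v.consequence)
    if v.consequence in _TIER2_INDEL:
        return TieredVariant(variant=v, tier=2, tier_basis=v.consequence)
    return None


def classify_all(variants: Iterable[VariantCall]) -> list[TieredVariant]:
    """Order-preserving classification, dropping non-reportable variants."""
    out = []
    for v in variants:
        t = classify(v)
        if t is not None:
            out.append(t)
    return out
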