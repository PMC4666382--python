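"""Junction classification: which species does a blocker actually block?

T4 DNA Ligase seals a nick in a DNA:RNA hybrid only when the strands
abut with no gap and the base pair at the junction is Watson-Crick.
Blocking of a non-target species is therefore governed by how its 5'
prefix anneals to the blocker overhang:

* register 0 - the species' 5' end abuts the blocker's free 3'-OH as a
  sealable nick.  A correct junction pair plus a long contiguous
  complementary run gives full blocking (BLOCKED); a shorter run gives
  partial blocking (PARTIAL).
* a first-position mismatch leaves the nick unsealable no matter how
  similar the rest of the prefix is: the species escapes (ESCAPE).
* register +1 - the species anneals one base downstream, leaving a
  one-base gap.  Gap sealing is inefficient, so at best PARTIAL.
* anything else (flaps from 5' extensions, gaps >= 2) is no junction.

Since the overhang is the exact reverse complement of the target's 5'
prefix, complementarity of a species to the overhang is equivalent to
identity with the target's prefix; all comparisons below are done in
the normalized RNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .config import ClassifierConfig
from .design import BlockerDesign, _longest_complementary_run
from .sequence_io import MatureMiRNA, normalize_rna

CLASSES = ("BLOCKED", "PARTIAL", "ESCAPE", "NONE")


class ClassificationUnsupportedError(NotImplementedError):
    """Raised for 3'-mode blockers.

    The 3' geometry is deprecated (large library-yield penalty, 3'
    isomiR sensitivity) and its off-target behaviour was never
    characterized; classify 5'-mode designs instead.
    """


@dataclass(frozen=True)
class JunctionCall:
    """Predicted annealing register and ligation outcome for one species."""

    species: str
    blocker_target: str
    register: int
    matched_prefix: int
    nick_pair_ok: bool
    blocking_class: str
    efficiency: float
    note: str = ""


def shared_prefix_len(a: MatureMiRNA | str, b: MatureMiRNA | str) -> int:
    """Length of the maximal identical 5' prefix of two sequences."""
    sa = normalize_rna(a.sequence if isinstance(a, MatureMiRNA) else a)
    sb = normalize_rna(b.sequence if isinstance(b, MatureMiRNA) else b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    n = 0
    for x, y in zip(sa, sb):
        if x != y:
            break
        n += 1
    return n


def _run_length(a: str, b: str, limit: int) -> int:
    """Contiguous matches of a vs b from position 0, capped at limit."""
    n = 0
    for x, y in zip(a, b):
        if x != y or n >= limit:
            break
        n += 1
    return min(n, limit)


def align_junction(
    blocker: BlockerDesign,
    species: MatureMiRNA,
    config: ClassifierConfig | None = None,
) -> JunctionCall:
    """Classify one species against one 5'-mode blocker.

    Registers 0 and +1 are the only productive geometries; ties prefer
    register 0.  ``matched_prefix`` is the contiguous complementary run
    from the junction (for ESCAPE, the run counted from position 2, the
    recorded near-miss).
    """
    if blocker.mode != "five_prime":
        raise ClassificationUnsupportedError(
            "off-target classification is defined for five_prime blockers only "
            "(the three_prime geometry is deprecated)"
        )
    cfg = config or ClassifierConfig()
    target = blocker.target_sequence
    k = blocker.overhang_length
    seq = species.sequence

    nick_ok = seq[0] == target[0]
    mp0 = _run_length(seq, target, k)
    downstream0 = _run_length(seq[1:], target[1:], k - 1)
    mp1 = _run_length(seq, target[1:], k - 1)

    note = ""
    if nick_ok and mp0 >= cfg.full_block_min:
        cls, register, mp = "BLOCKED", 0, mp0
    elif nick_ok and mp0 >= cfg.partial_min:
        cls, register, mp = "PARTIAL", 0, mp0
        if mp1 >= cfg.partial_min:
            note = "gap register +1 also plausible; register 0 preferred by tie-break"
    elif not nick_ok and downstream0 >= cfg.partial_min:
        cls, register, mp = "ESCAPE", 0, downstream0
        note = "junction base pair mismatch; nick not sealable"
    elif mp1 >= cfg.partial_min:
        cls, register, mp = "PARTIAL", 1, mp1
        note = "one-base gap between species 5' end and blocker 3' end"
    else:
        cls, register, mp = "NONE", 0, mp0

    return JunctionCall(
        species=species.name,
        blocker_target=blocker.target_name,
        register=register,
        matched_prefix=mp,
        nick_pair_ok=nick_ok,
        blocking_class=cls,
        efficiency=cfg.efficiency(cls),
        note=note,
    )


def classify_all(
    blocker: BlockerDesign,
    mirna_set: Sequence[MatureMiRNA],
    config: ClassifierConfig | None = None,
) -> list[JunctionCall]:
    """One JunctionCall per species, in input order."""
    return [align_junction(blocker, sp, config=config) for sp in mirna_set]


def summarize_calls(calls: Iterable[JunctionCall]) -> dict[str, int]:
    """Counts by blocking class, all four classes always present."""
    out = {c: 0 for c in CLASSES}
    for call in calls:
        out[call.blocking_class] += 1
    return out


def calls_to_frame(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "blocker_target": c.blocker_target,
                "register": c.register,
                "matched_prefix": c.matched_prefix,
                "nick_pair_ok": c.nick_pair_ok,
                "class": c.blocking_class,
                "efficiency": c.efficiency,
                "note": c.note,
            }
            for c in calls
        ]
    )


def isoform_adjust(
    call: JunctionCall, offset: int, config: ClassifierConfig | None = None
) -> JunctionCall:
    """Re-classify a call for a 5' isomiR shifted by ``offset`` bases.

    A +1 shift (trimmed 5' end) moves the junction to the one-base gap
    register: at most PARTIAL.  A -1 shift (extended 5' end) leaves an
    unligatable 5' flap: the species escapes.  Shifts of two or more
    bases destroy the junction entirely.
    """
    cfg = config or ClassifierConfig()
    if offset == 0:
        return call
    productive = call.blocking_class in ("BLOCKED", "PARTIAL")
    if offset == 1:
        cls = "PARTIAL" if productive else "NONE"
        new = dict(
            register=1,
            nick_pair_ok=False,
            matched_prefix=max(0, call.matched_prefix - 1),
            note="5' trimmed isomiR: one-base gap register",
        )
    elif offset == -1:
        cls = "ESCAPE" if productive else "NONE"
        new = dict(
            register=-1,
            nick_pair_ok=False,
            note="5' extended isomiR: unligatable flap at the junction",
        )
    else:
        cls = "NONE"
        new = dict(
            register=offset,
            nick_pair_ok=False,
            matched_prefix=0,
            note=f"5' shift of {offset:+d} bases: no productive junction",
        )
    return replace(call, blocking_class=cls, efficiency=cfg.efficiency(cls), **new)


def isoform_weighted_survival(
    call: JunctionCall,
    offsets_and_weights: Sequence[tuple[int, float]],
    config: ClassifierConfig | None = None,
) -> float:
    """Aggregate fraction of a species' reads surviving blocking when a
    weighted mixture of 5' isomiRs is present; the weight remainder is
    the canonical form."""
    cfg = config or ClassifierConfig()
    wsum = sum(w for _, w in offsets_and_weights)
    if wsum > 1 + 1e-9:
        raise ValueError(f"isoform weights sum to {wsum} > 1")
    survival = (1.0 - wsum) * (1.0 - call.efficiency)
    for offset, w in offsets_and_weights:
        survival += w * (1.0 - isoform_adjust(call, offset, cfg).efficiency)
    return survival


@dataclass
class MultiplexResult:
    calls: list[JunctionCall]
    flagged_pairs: list[tuple[str, str, int]]  # (target_a, target_b, run length)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def multiplex(
    calls_per_blocker: Sequence[Sequence[JunctionCall]],
    blockers: Sequence[BlockerDesign] | None = None,
) -> MultiplexResult:
    """Combine per-blocker calls under union semantics (no interaction).

    Per species the call with the highest efficiency wins (ties go to
    the earlier blocker).  When the designs are supplied, blocker pairs
    whose overhangs are mutually complementary over >= 8 contiguous
    bases are flagged (they would titrate each other out in solution).
    """
    if not calls_per_blocker:
        return MultiplexResult([], [])
    ref = [c.species for c in calls_per_blocker[0]]
    for calls in calls_per_blocker[1:]:
        if [c.species for c in calls] != ref:
            raise ValueError("call lists cover inconsistent species sets")
    merged = [
        max(per_species, key=lambda c: c.efficiency)
        for per_species in zip(*calls_per_blocker)
    ]
    flagged: list[tuple[str, str, int]] = []
    if blockers is not None:
        for i in range(len(blockers)):
            for j in range(i + 1, len(blockers)):
                run = _longest_complementary_run(
                    blockers[i].overhang, blockers[j].overhang
                )
                if run >= 8:
                    flagged.append(
                        (blockers[i].target_name, blockers[j].target_name, run)
                    )
    return MultiplexResult(list(merged), flagged)
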