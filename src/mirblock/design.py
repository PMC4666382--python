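"""Blocker oligonucleotide construction.

A blocker is a self-complementary DNA hairpin whose single-stranded
overhang is the reverse complement of one terminus of the targeted
mature miRNA.  In the 5' geometry the overhang sits at the hairpin's 5'
end, a C3 spacer caps that terminus, and the free 3'-OH of the hairpin
abuts the annealed miRNA's 5' phosphate as a ligase-sealable nick; once
T4 DNA Ligase seals the nick the target can no longer receive a 5'
adaptor and drops out of the amplified library.  The 3' geometry (3'
overhang, 5' phosphate, 3' C3 spacer) blocks from the other end; it is
retained for completeness but deprecated because it costs roughly
five-fold in final library yield and is more exposed to 3' isomiR
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .config import ClassifierConfig, DesignConfig
from .sequence_io import MatureMiRNA

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

MOD_CODES = {("5'", "C3_spacer"): "/5SpC3/", ("5'", "phosphate"): "/5Phos/",
             ("3'", "C3_spacer"): "/3SpC3/"}


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement into the DNA alphabet (RNA input accepted)."""
    return str(Seq(seq.upper().replace("U", "T")).reverse_complement())


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature, 2(A+T) + 4(G+C) degC.

    A rough screen for short oligos; informational only.
    """
    s = seq.upper().replace("U", "T")
    at = sum(s.count(b) for b in "AT")
    gc = sum(s.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class BlockerDesign:
    """An order-ready blocker hairpin for one target miRNA."""

    target_name: str
    target_sequence: str  # RNA, canonical mature form
    mode: str  # "five_prime" | "three_prime"
    overhang: str
    overhang_length: int
    stem: str
    loop: str
    full_sequence: str
    modifications: tuple[tuple[str, str], ...]
    overhang_tm: float

    def __post_init__(self) -> None:
        if self.mode not in ("five_prime", "three_prime"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for part in (self.overhang, self.stem, self.loop):
            bad = set(part) - DNA_ALPHABET
            if bad:
                raise ValueError(f"non-DNA characters in oligo part: {sorted(bad)}")
        hairpin = self.stem + self.loop + reverse_complement_dna(self.stem)
        expected = (
            self.overhang + hairpin if self.mode == "five_prime" else hairpin + self.overhang
        )
        if self.full_sequence != expected:
            raise ValueError("full_sequence inconsistent with parts")


def design_blocker(
    target: MatureMiRNA,
    mode: str = "five_prime",
    overhang_length: int | None = None,
    stem: str | None = None,
    loop: str | None = None,
    config: DesignConfig | None = None,
) -> BlockerDesign:
    """Design a blocker hairpin against ``target``.

    The overhang is the DNA reverse complement of the first
    ``overhang_length`` bases of the target (5' mode) or the last ones
    (3' mode).  Stem and loop default to an 8-bp GC-balanced stem and a
    GAAA tetraloop and may be overridden.
    """
    cfg = config or DesignConfig()
    k = cfg.overhang_length if overhang_length is None else int(overhang_length)
    stem = (cfg.stem if stem is None else stem).upper()
    loop = (cfg.loop if loop is None else loop).upper()

    if k > len(target):
        raise ValueError(
            f"overhang_length {k} exceeds target length {len(target)} for {target.name}"
        )
    if k < 8:
        raise ValueError(f"overhang_length {k} < 8: too short to form a stable junction")
    if not 10 <= k <= 14:
        logger.warning("overhang_length %d outside the validated 10-14 range", k)
    if set(stem) - DNA_ALPHABET or set(loop) - DNA_ALPHABET:
        raise ValueError("stem/loop must be DNA (A/C/G/T)")
    if len(stem) < 4:
        raise ValueError("stem too short to form a hairpin (need >= 4 bp)")
    if len(loop) < 3:
        raise ValueError("loop length must be >= 3")

    if mode == "five_prime":
        overhang = reverse_complement_dna(target.sequence[:k])
        full = overhang + stem + loop + reverse_complement_dna(stem)
        mods = (("5'", "C3_spacer"),)  # 3' terminus stays a free, ligatable OH
    elif mode == "three_prime":
        overhang = reverse_complement_dna(target.sequence[-k:])
        full = stem + loop + reverse_complement_dna(stem) + overhang
        mods = (("5'", "phosphate"), ("3'", "C3_spacer"))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return BlockerDesign(
        target_name=target.name,
        target_sequence=target.sequence,
        mode=mode,
        overhang=overhang,
        overhang_length=k,
        stem=stem,
        loop=loop,
        full_sequence=full,
        modifications=mods,
        overhang_tm=wallace_tm(overhang),
    )


def _longest_complementary_run(a: str, b: str) -> int:
    """Longest contiguous stretch of ``a`` that can base-pair with ``b``
    in antiparallel orientation (longest common substring of a and
    revcomp(b))."""
    rb = reverse_complement_dna(b)
    best = 0
    n, m = len(a), len(rb)
    for i in range(n):
        for j in range(m):
            run = 0
            while i + run < n and j + run < m and a[i + run] == rb[j + run]:
                run += 1
            best = max(best, run)
    return best


@dataclass
class DesignReport:
    target_name: str
    self_dimer: bool
    overhang_stem_crosspair: bool
    tm_out_of_window: bool
    overhang_tm: float
    nontarget_blocked: int
    nontarget_blocked_names: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def flags(self) -> list[str]:
        out = []
        if self.self_dimer:
            out.append("overhang self-dimerization")
        if self.overhang_stem_crosspair:
            out.append("overhang-stem cross-pairing")
        if self.tm_out_of_window:
            out.append("overhang Tm outside window")
        return out


def check_design(
    design: BlockerDesign,
    mirna_set: Sequence[MatureMiRNA] = (),
    config: DesignConfig | None = None,
    classifier: ClassifierConfig | None = None,
) -> DesignReport:
    """Screen a design for pathological structure and off-target blocking.

    Report-only: nothing here raises.  Flags overhang self-dimerization
    (>= 6 contiguous self-complementary bases), overhang pairing with
    either hairpin arm (>= 6 contiguous bases), an overhang Tm outside
    the configured window, and the number of non-target species the
    junction classifier predicts as fully BLOCKED.
    """
    from .offtarget import classify_all  # deferred: offtarget imports design types

    cfg = config or DesignConfig()
    oh = design.overhang
    arms = design.stem + reverse_complement_dna(design.stem)
    self_dimer = _longest_complementary_run(oh, oh) >= 6
    crosspair = _longest_complementary_run(oh, arms) >= 6
    lo, hi = cfg.tm_window
    tm_out = not lo <= design.overhang_tm <= hi

    blocked_names: list[str] = []
    if design.mode == "five_prime" and mirna_set:
        calls = classify_all(design, mirna_set, config=classifier)
        blocked_names = [
            c.species
            for c in calls
            if c.blocking_class == "BLOCKED" and c.species != design.target_name
        ]

    warnings: list[str] = []
    if design.mode == "three_prime":
        warnings.append(
            "three_prime designs are deprecated: ~5x lower final library yield and "
            "greater sensitivity to 3' isomiR variation"
        )

    return DesignReport(
        target_name=design.target_name,
        self_dimer=self_dimer,
        overhang_stem_crosspair=crosspair,
        tm_out_of_window=tm_out,
        overhang_tm=design.overhang_tm,
        nontarget_blocked=len(blocked_names),
        nontarget_blocked_names=blocked_names,
        warnings=warnings,
    )


def render_oligo(design: BlockerDesign) -> str:
    """Full sequence with vendor-style modification codes inlined."""
    seq = design.full_sequence
    for terminus, code in design.modifications:
        tag = MOD_CODES[(terminus, code)]
        seq = tag + seq if terminus == "5'" else seq + tag
    return seq


def render_order_sheet(designs: Iterable[BlockerDesign], path: str | Path) -> None:
    """Write a TSV order sheet: name, modified sequence, mode, overhang length."""
    lines = ["name\tsequence_with_modifications\tmode\toverhang_length"]
    for d in designs:
        lines.append(
            f"{d.target_name}_blocker\t{render_oligo(d)}\t{d.mode}\t{d.overhang_length}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
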