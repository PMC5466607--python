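"""In-silico cDNA-AFLP: digestion, selective amplification, size selection.

Predicts the band profile a transcript set would produce on an AFLP gel:
every transcript is cut with EcoRI and MseI, fragments carrying one EcoRI
and one MseI end are kept (standard AFLP chemistry amplifies the mixed
class; rare EcoRI-EcoRI and MseI-MseI products are suppressed), fragments
whose bases adjacent to the site remnants match the selective 3' extensions
of the primer pair survive amplification, and fragments inside the size
window co-migrate into bands keyed by length.

Coordinates are 0-based half-open on the transcript top strand; cut
positions refer to the top strand.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqRecord import SeqRecord

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class EnzymeEnd(enum.Enum):
    """What produced a fragment end: an enzyme cut or the molecule terminus."""

    ECORI = "EcoRI"
    MSEI = "MseI"
    TERMINUS = "terminus"


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction enzyme with a fixed cut offset within its site.

    ``cut_offset`` is the position of the cut within the recognition site,
    5'->3' on the top strand (EcoRI G^AATTC -> offset 1).
    """

    name: str
    recognition_site: str
    cut_offset: int
    end: EnzymeEnd

    def __post_init__(self) -> None:
        if not self.recognition_site:
            raise ValueError("recognition site must be non-empty")
        if not set(self.recognition_site) <= _DNA:
            raise ValueError(
                f"recognition site {self.recognition_site!r} contains "
                "non-ACGT characters"
            )
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError("cut_offset outside the recognition site")


ECORI = RestrictionEnzyme("EcoRI", "GAATTC", 1, EnzymeEnd.ECORI)
MSEI = RestrictionEnzyme("MseI", "TTAA", 1, EnzymeEnd.MSEI)

#: Double-strand site remnants left on a fragment after cutting and ligation,
#: keyed by (enzyme end, side of the fragment the end is on).  E.g. EcoRI
#: G^AATTC leaves "AATTC" at the start of the downstream fragment and a bare
#: "G" at the end of the upstream one.
_REMNANT = {
    (EnzymeEnd.ECORI, "left"): "AATTC",
    (EnzymeEnd.ECORI, "right"): "G",
    (EnzymeEnd.MSEI, "left"): "TAA",
    (EnzymeEnd.MSEI, "right"): "T",
}


@dataclass(frozen=True)
class PrimerSpec:
    """A selective AFLP primer: adapter-derived core plus a 3' extension.

    ``selective_ext`` length 0, 1 or 3 matches the +0/+1/+3 primer designs.
    """

    enzyme_end: EnzymeEnd
    core: str
    selective_ext: str = ""

    def __post_init__(self) -> None:
        if self.enzyme_end is EnzymeEnd.TERMINUS:
            raise ValueError("primer must target an enzyme end")
        if len(self.selective_ext) not in (0, 1, 3):
            raise ValueError("selective extension must have length 0, 1 or 3")
        if not set(self.selective_ext) <= _DNA:
            raise ValueError("selective extension contains non-ACGT characters")


# The published primer cores (adapter + site remnant, written 5'->3').
ECORI_CORE = "TACTGCGTACCAATTC"
MSEI_CORE = "GACGATGAGTCCTGAGTAA"


def ecoRI_primer(ext: str = "") -> PrimerSpec:
    return PrimerSpec(EnzymeEnd.ECORI, ECORI_CORE, ext)


def mseI_primer(ext: str = "") -> PrimerSpec:
    return PrimerSpec(EnzymeEnd.MSEI, MSEI_CORE, ext)


@dataclass(frozen=True)
class DigestFragment:
    """One restriction fragment of a transcript."""

    source_id: str
    start: int
    end: int
    left_enzyme: EnzymeEnd
    right_enzyme: EnzymeEnd
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment must have end > start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length disagrees with coordinates")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def end_types(self) -> frozenset[EnzymeEnd]:
        return frozenset((self.left_enzyme, self.right_enzyme))

    @property
    def duplex_length(self) -> int:
        """Strand-independent extent of the double-stranded fragment.

        Both enzymes cut off-centre and leave 5' overhangs, so the top- and
        bottom-strand lengths of one fragment differ; the duplex extent
        (leftmost to rightmost cut over both strands) adds the overhang
        excess at each cut end and is invariant under reverse complement.
        """
        excess = {EnzymeEnd.ECORI: 4, EnzymeEnd.MSEI: 2, EnzymeEnd.TERMINUS: 0}
        return len(self) + excess[self.right_enzyme]


@dataclass(frozen=True)
class PredictedBand:
    """Co-migrating fragments observed as a single gel band."""

    primer_pair: tuple[PrimerSpec, PrimerSpec]
    size_bp: int
    member_fragments: tuple[DigestFragment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("band size must be positive")


def _check_dna(sequence: str) -> None:
    m = re.search("[^ACGT]", sequence)
    if m:
        raise ValueError(
            f"non-ACGT character {sequence[m.start()]!r} at position {m.start()}"
        )


def locate_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut positions of ``enzyme`` in ``sequence``, sorted ascending.

    Overlapping occurrences of the recognition site are all reported.
    Ambiguity codes are rejected (the engine works on called bases only).
    """
    _check_dna(sequence)
    site = enzyme.recognition_site
    positions = []
    i = sequence.find(site)
    while i != -1:
        positions.append(i + enzyme.cut_offset)
        i = sequence.find(site, i + 1)
    return positions


def digest(
    sequence: str,
    enzymes: Sequence[RestrictionEnzyme],
    source_id: str = "",
) -> list[DigestFragment]:
    """Cut ``sequence`` at every site of every enzyme (complete digestion).

    Fragments tile the sequence exactly; internal boundaries are labelled
    with the enzyme that cut them and the outermost ends with TERMINUS.
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    if not sequence:
        return []
    cuts: dict[int, EnzymeEnd] = {}
    for enz in enzymes:
        for pos in locate_sites(sequence, enz):
            if pos in cuts and cuts[pos] is not enz.end:
                raise ValueError(
                    f"conflicting cuts by two enzymes at position {pos}"
                )
            cuts[pos] = enz.end
    # cuts at the very ends produce no new fragment boundary
    bounds = sorted(p for p in cuts if 0 < p < len(sequence))
    starts = [0, *bounds]
    ends = [*bounds, len(sequence)]
    fragments = []
    for s, e in zip(starts, ends):
        fragments.append(
            DigestFragment(
                source_id=source_id,
                start=s,
                end=e,
                left_enzyme=cuts.get(s, EnzymeEnd.TERMINUS) if s > 0 else EnzymeEnd.TERMINUS,
                right_enzyme=cuts.get(e, EnzymeEnd.TERMINUS) if e < len(sequence) else EnzymeEnd.TERMINUS,
                sequence=sequence[s:e],
            )
        )
    return fragments


def _end_matches(
    sequence: str, side: str, end: EnzymeEnd, ext: str
) -> bool:
    """Do the bases interior to the site remnant match a selective extension?

    At a left end the primer reads the top strand directly; at a right end it
    reads the bottom strand, so the interior bases match the extension in
    reverse complement.
    """
    if not ext:
        return True
    remnant = _REMNANT[(end, side)]
    k = len(ext)
    if side == "left":
        if not sequence.startswith(remnant):
            return False
        interior = sequence[len(remnant) : len(remnant) + k]
        return interior == ext
    if not sequence.endswith(remnant):
        return False
    lo = len(sequence) - len(remnant) - k
    if lo < 0:
        return False
    interior = sequence[lo : len(sequence) - len(remnant)]
    return _revcomp(interior) == ext


def selective_filter(
    fragment: DigestFragment,
    ecoRI_primer: PrimerSpec,
    mseI_primer: PrimerSpec,
) -> bool:
    """Would the fragment amplify under this selective primer pair?

    The fragment must carry one EcoRI end and one MseI end; each primer's 3'
    selective extension must match the fragment bases immediately interior
    to the corresponding site remnant (read on the strand the primer
    extends along, hence reverse-complemented at the fragment's right end).
    """
    if fragment.end_types != {EnzymeEnd.ECORI, EnzymeEnd.MSEI}:
        raise ValueError(
            "selective_filter requires a fragment with one EcoRI and one "
            f"MseI end, got ({fragment.left_enzyme.value}, "
            f"{fragment.right_enzyme.value})"
        )
    sides = {fragment.left_enzyme: "left", fragment.right_enzyme: "right"}
    return _end_matches(
        fragment.sequence, sides[EnzymeEnd.ECORI], EnzymeEnd.ECORI,
        ecoRI_primer.selective_ext,
    ) and _end_matches(
        fragment.sequence, sides[EnzymeEnd.MSEI], EnzymeEnd.MSEI,
        mseI_primer.selective_ext,
    )


def predict_profile(
    transcripts: Iterable[SeqRecord | tuple[str, str]],
    ecoRI_primer: PrimerSpec,
    mseI_primer: PrimerSpec,
    size_window: tuple[int, int] = (100, 600),
    size_offset: int = 0,
    amplifiable_only: bool = True,
) -> list[PredictedBand]:
    """Predict the gel band profile of a transcript set for one primer pair.

    Parameters
    ----------
    transcripts
        Biopython ``SeqRecord`` objects or plain ``(id, sequence)`` pairs.
    size_window
        Inclusive band-size range retained, in bp; the default reflects the
        usual AFLP scoring range on polyacrylamide gels.
    size_offset
        Constant added to the fragment length to obtain the band size
        (adapter/primer contribution); 0 reports raw fragment lengths.
    amplifiable_only
        Keep only EcoRI-MseI fragments (the class the primer pair amplifies
        exponentially).  When False, same-end fragments are also scored,
        with the matching primer applied to both ends.

    Returns
    -------
    list of PredictedBand, sorted by size descending (gel order, largest
    fragments migrate least); co-migrating fragments share one band.
    """
    lo, hi = size_window
    if lo < 1 or lo > hi:
        raise ValueError("size window must satisfy 1 <= min <= max")
    by_size: dict[int, list[DigestFragment]] = {}
    for rec in transcripts:
        if isinstance(rec, SeqRecord):
            rid, seq = rec.id, str(rec.seq).upper()
        else:
            rid, seq = rec[0], str(rec[1]).upper()
        for frag in digest(seq, [ECORI, MSEI], source_id=rid):
            ends = frag.end_types
            if EnzymeEnd.TERMINUS in ends:
                continue
            if ends == {EnzymeEnd.ECORI, EnzymeEnd.MSEI}:
                if not selective_filter(frag, ecoRI_primer, mseI_primer):
                    continue
            elif amplifiable_only:
                continue
            else:
                primer = (
                    ecoRI_primer if ends == {EnzymeEnd.ECORI} else mseI_primer
                )
                if not all(
                    _end_matches(frag.sequence, side, frag.left_enzyme if side == "left" else frag.right_enzyme, primer.selective_ext)
                    for side in ("left", "right")
                ):
                    continue
            size = len(frag) + size_offset
            if lo <= size <= hi:
                by_size.setdefault(size, []).append(frag)
    pair = (ecoRI_primer, mseI_primer)
    return [
        PredictedBand(pair, size, tuple(by_size[size]))
        for size in sorted(by_size, reverse=True)
    ]


def profile_to_rows(bands: Sequence[PredictedBand]) -> list[dict]:
    """Flatten a band profile into TSV-ready rows."""
    rows = []
    for band in bands:
        eco, mse = band.primer_pair
        rows.append(
            {
                "primer_pair": f"E+{eco.selective_ext or '0'}/M+{mse.selective_ext or '0'}",
                "size_bp": band.size_bp,
                "n_fragments": len(band.member_fragments),
                "fragment_ids": ",".join(
                    f"{f.source_id}:{f.start}-{f.end}"
                    for f in band.member_fragments
                ),
            }
        )
    return rows
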