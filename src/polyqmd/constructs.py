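"""Huntingtin exon1 construct assembly.

Three polypeptide constructs are modelled, each at a variable polyglutamine
repeat length ``n``:

``QN``
    the bare polyglutamine homopolymer Q_n;
``XN1``
    full huntingtin exon 1 — the 17-residue N-terminal segment (Nt17),
    the polyQ run, an 11-proline run (P11), a 17-residue proline-rich
    tether, a 10-proline run (P10) and a 12-residue C-terminus;
``XN1_DP``
    exon 1 with both polyproline runs deleted (XN1-ΔpolyP).

The non-polyQ parts come from a packaged FASTA fixture holding the first 90
residues of human huntingtin (the 23-repeat form); the fixture is validated
against the expected region lengths (17/23/11/17/10/12) at load time.
Residue indexing is 0-based half-open throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

__all__ = [
    "ConstructKind",
    "RegionSpec",
    "ConstructModel",
    "build_construct",
    "region_mask",
    "load_exon1_fixture",
]


class ConstructKind(enum.Enum):
    QN = "QN"
    XN1 = "XN1"
    XN1_DP = "XN1_DP"


#: Region names in N→C order for full exon1, with fixture lengths.
_XN1_REGION_LENGTHS = (
    ("NT17", 17),
    ("POLYQ", 23),  # fixture repeat count; replaced by n at build time
    ("P11", 11),
    ("TETHER17", 17),
    ("P10", 10),
    ("CTERM12", 12),
)

REGION_NAMES = tuple(name for name, _ in _XN1_REGION_LENGTHS)
FIXTURE_REPEATS = 23


@dataclass(frozen=True)
class RegionSpec:
    """Half-open residue index range [start, end) of a named sequence region."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown region name {self.name!r}")
        if self.end <= self.start:
            raise ValueError("region must have end > start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConstructModel:
    """A specific polypeptide model: construct kind + repeat length + sequence."""

    kind: ConstructKind
    n_repeats: int
    sequence: str
    regions: tuple[RegionSpec, ...]

    def __post_init__(self) -> None:
        pos = 0
        for reg in self.regions:
            if reg.start != pos:
                raise ValueError("regions must tile the sequence without gaps")
            pos = reg.end
        if pos != len(self.sequence):
            raise ValueError("regions must cover the full sequence")

    @property
    def name(self) -> str:
        n = self.n_repeats
        return {
            ConstructKind.QN: f"Q{n}",
            ConstructKind.XN1: f"XN1Q{n}",
            ConstructKind.XN1_DP: f"XN1Q{n}-dP",
        }[self.kind]

    def __len__(self) -> int:
        return len(self.sequence)


def load_exon1_fixture() -> dict[str, str]:
    """Load the packaged exon1 sequence and split it into named regions.

    Returns a mapping region name → subsequence. Raises ``ValueError`` if the
    fixture does not match the expected region lengths or residue content.
    """
    ref = resources.files("polyqmd.data").joinpath("htt_exon1_90.fasta")
    with ref.open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    seq = str(record.seq)
    if len(seq) != sum(n for _, n in _XN1_REGION_LENGTHS):
        raise ValueError(f"exon1 fixture has {len(seq)} residues, expected 90")
    parts: dict[str, str] = {}
    pos = 0
    for name, length in _XN1_REGION_LENGTHS:
        parts[name] = seq[pos : pos + length]
        pos += length
    if set(parts["POLYQ"]) != {"Q"}:
        raise ValueError("fixture polyQ region is not all glutamine")
    if set(parts["P11"]) != {"P"} or set(parts["P10"]) != {"P"}:
        raise ValueError("fixture polyP regions are not all proline")
    return parts


def build_construct(kind: ConstructKind | str, n: int) -> ConstructModel:
    """Assemble a construct model with ``n`` glutamine repeats.

    ``QN`` is the bare homopolymer; ``XN1`` is the full exon1 sequence with
    its polyQ run replaced by ``n`` glutamines; ``XN1_DP`` additionally has
    the P11 and P10 runs deleted seamlessly.
    """
    if isinstance(kind, str):
        try:
            kind = ConstructKind[kind]
        except KeyError:
            raise ValueError(f"unknown construct kind {kind!r}") from None
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"repeat count must be a positive integer, got {n!r}")

    if kind is ConstructKind.QN:
        seq = "Q" * n
        regions = (RegionSpec("POLYQ", 0, n),)
        return ConstructModel(kind, n, seq, regions)

    parts = load_exon1_fixture()
    parts = dict(parts, POLYQ="Q" * n)
    if kind is ConstructKind.XN1_DP:
        order = ("NT17", "POLYQ", "TETHER17", "CTERM12")
    else:
        order = REGION_NAMES
    regions = []
    pos = 0
    seq_parts = []
    for name in order:
        sub = parts[name]
        regions.append(RegionSpec(name, pos, pos + len(sub)))
        seq_parts.append(sub)
        pos += len(sub)
    return ConstructModel(kind, n, "".join(seq_parts), tuple(regions))


def region_mask(model: ConstructModel, name: str) -> range:
    """0-based half-open residue index range of a named region.

    Raises ``KeyError`` if the region is absent from this construct (e.g.
    P11 on a QN model).
    """
    for reg in model.regions:
        if reg.name == name:
            return range(reg.start, reg.end)
    raise KeyError(f"region {name!r} not present in {model.name}")
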