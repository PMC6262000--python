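"""Design of rolling-circle FISH probe sets.

A probe set for one gene consists of:

* a series of 80 nt ODNs, each = 30 nt reverse complement of a transcript
  window (the targeting arm) + a TTTT hinge + a shared 46 nt docking
  sequence chosen to be orthogonal to the transcriptome (no shared k-mer,
  default k = 15, on either strand);
* one padlock probe whose two terminal arms, read 3′-arm-then-5′-arm,
  reverse-complement the docking sequence contiguously, so the ends abut
  on the docking sequence and can be ligated into a circle; its backbone
  carries a transcript-specific barcode;
* one fluorescently labeled detection oligo identical to the barcode, so
  it hybridizes to the barcode's reverse complement repeated throughout
  the rolling-circle amplification product.

Because all ODNs of a set share one docking sequence, a single padlock
species detects the whole set. RNA inputs are handled in DNA alphabet
(U→T). All randomized choices are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .errors import CapacityError, ExhaustionError, InvalidInputError, InvalidParameterError

__all__ = [
    "Odn",
    "Padlock",
    "DetectionOligo",
    "ProbeSet",
    "tile_target",
    "generate_docking",
    "assemble_odn",
    "design_padlock",
    "design_probeset",
    "validate_probeset",
    "random_barcode",
]

HINGE = "TTTT"
_ALPHABET = set("ACGT")
# fixed backbone linkers flanking the barcode (arbitrary, low-structure)
_LINKER_5 = "TCACGATTCC"
_LINKER_3 = "CCTATAGTGA"


def _normalize(seq: str) -> str:
    """Uppercase, RNA→DNA; reject ambiguity codes."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise InvalidInputError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _kmers(seq: str, k: int) -> Iterable[str]:
    return (seq[i : i + k] for i in range(len(seq) - k + 1))


@dataclass(frozen=True)
class Odn:
    """One targeting oligo: complement arm + TTTT hinge + docking sequence."""

    complement_region: str
    docking_region: str
    target_start: int = 0
    target_end: int = 0
    hinge: str = HINGE

    @property
    def sequence(self) -> str:
        return self.complement_region + self.hinge + self.docking_region


@dataclass(frozen=True)
class Padlock:
    """Padlock probe: 5′ arm + barcode-carrying backbone + 3′ arm.

    The linear sequence runs 5′→3′ as ``arm_5prime + backbone +
    arm_3prime``; hybridized to the docking sequence the two terminal arms
    sit end-to-end (3′ arm first along the docking strand), forming a
    ligatable junction.
    """

    arm_5prime: str
    arm_3prime: str
    barcode: str
    backbone: str

    @property
    def sequence(self) -> str:
        return self.arm_5prime + self.backbone + self.arm_3prime


@dataclass(frozen=True)
class DetectionOligo:
    """Fluorescent readout oligo; its sequence equals the barcode."""

    sequence: str
    fluorophore: str = "Cy3"


@dataclass(frozen=True)
class ProbeSet:
    gene_id: str
    odns: tuple[Odn, ...]
    padlock: Padlock
    detection_oligo: DetectionOligo
    report: dict = field(default_factory=dict)


def tile_target(
    transcript: str,
    n_odns: int,
    *,
    tile_length: int = 30,
    min_gap: int = 2,
    gc_bounds: tuple[float, float] = (0.3, 0.7),
    tm_bounds: tuple[float, float] | None = None,
) -> list[tuple[str, int, int]]:
    """Select non-overlapping target windows and emit their complements.

    Scans the transcript 5′→3′, greedily accepting each ``tile_length``
    window that passes the GC (and optional nearest-neighbor Tm) filters
    and starts at least ``min_gap`` nt after the previous accepted window,
    until ``n_odns`` windows are placed. Deterministic.

    Returns ``(complement_region, start, end)`` triples where
    ``complement_region`` is the reverse complement of
    ``transcript[start:end]``. Raises :class:`CapacityError` (carrying the
    achievable count) if the transcript cannot host ``n_odns`` tiles.
    """
    t = _normalize(transcript)
    if n_odns < 1:
        raise InvalidParameterError("n_odns must be >= 1")
    if tile_length < 1 or len(t) < tile_length:
        raise CapacityError(
            f"transcript ({len(t)} nt) shorter than tile length {tile_length}",
            achievable=0,
        )
    lo, hi = gc_bounds
    tiles: list[tuple[str, int, int]] = []
    pos = 0
    while pos + tile_length <= len(t) and len(tiles) < n_odns:
        window = t[pos : pos + tile_length]
        gc = gc_fraction(window)
        ok = lo <= gc <= hi
        if ok and tm_bounds is not None:
            tm = MeltingTemp.Tm_NN(Seq(window))
            ok = tm_bounds[0] <= tm <= tm_bounds[1]
        if ok:
            tiles.append((_revcomp(window), pos, pos + tile_length))
            pos += tile_length + min_gap
        else:
            pos += 1
    if len(tiles) < n_odns:
        raise CapacityError(
            f"only {len(tiles)} of {n_odns} tiles fit the transcript under the filters",
            achievable=len(tiles),
        )
    return tiles


def generate_docking(
    transcriptome: Mapping[str, str] | Sequence[str],
    *,
    length: int = 46,
    k: int = 15,
    gc_bounds: tuple[float, float] = (0.4, 0.6),
    max_homopolymer: int = 4,
    n_candidates: int = 10000,
    seed: int = 0,
) -> str:
    """Generate a docking sequence orthogonal to a transcriptome.

    Random candidates of the given length are screened until one shares no
    k-mer with the transcriptome on either strand, has GC content within
    ``gc_bounds`` and homopolymer runs of at most ``max_homopolymer``.
    Deterministic given the seed; raises :class:`ExhaustionError` if no
    candidate passes within ``n_candidates`` tries.
    """
    if k > length:
        raise InvalidParameterError("k must be <= docking length")
    seqs = transcriptome.values() if isinstance(transcriptome, Mapping) else transcriptome
    forbidden: set[str] = set()
    for s in seqs:
        s = _normalize(s)
        forbidden.update(_kmers(s, k))
        forbidden.update(_kmers(_revcomp(s), k))
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    lo, hi = gc_bounds
    for _ in range(n_candidates):
        cand = "".join(rng.choice(bases, size=length))
        if not lo <= gc_fraction(cand) <= hi:
            continue
        if _max_homopolymer(cand) > max_homopolymer:
            continue
        if any(m in forbidden for m in _kmers(cand, k)):
            continue
        return cand
    raise ExhaustionError(
        f"no orthogonal docking sequence found in {n_candidates} candidates"
    )


def assemble_odn(
    complement_region: str,
    docking_region: str,
    *,
    target_start: int = 0,
    target_end: int = 0,
    complement_length: int = 30,
    docking_length: int = 46,
) -> Odn:
    """Concatenate complement arm, TTTT hinge and docking sequence.

    Under defaults the full oligo is 30 + 4 + 46 = 80 nt with the hinge at
    positions 31–34 (1-based).
    """
    comp = _normalize(complement_region)
    dock = _normalize(docking_region)
    if len(comp) != complement_length:
        raise InvalidInputError(
            f"complement region must be {complement_length} nt, got {len(comp)}"
        )
    if len(dock) != docking_length:
        raise InvalidInputError(
            f"docking region must be {docking_length} nt, got {len(dock)}"
        )
    return Odn(comp, dock, target_start=target_start, target_end=target_end)


def design_padlock(
    docking_region: str,
    barcode: str,
    *,
    arm_split: int = 23,
) -> Padlock:
    """Design the padlock probe for a docking sequence.

    The reverse complement of the docking sequence is split at
    ``arm_split`` into the 3′ arm (first part along the docking strand)
    and 5′ arm, so that reading 3′-arm-then-5′-arm and reverse-complementing
    recovers the docking sequence exactly — the two probe ends then abut
    when hybridized (ligatable junction). The barcode is embedded in the
    backbone between fixed linkers.
    """
    dock = _normalize(docking_region)
    bc = _normalize(barcode)
    if not 0 < arm_split < len(dock):
        raise InvalidParameterError("arm_split must be strictly inside the docking region")
    rc = _revcomp(dock)
    arm_3prime = rc[:arm_split]
    arm_5prime = rc[arm_split:]
    backbone = _LINKER_5 + bc + _LINKER_3
    return Padlock(
        arm_5prime=arm_5prime, arm_3prime=arm_3prime, barcode=bc, backbone=backbone
    )


def random_barcode(length: int = 20, *, max_homopolymer: int = 4, seed: int = 0) -> str:
    """Random ACGT barcode with bounded homopolymer runs."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(10000):
        bc = "".join(rng.choice(bases, size=length))
        if _max_homopolymer(bc) <= max_homopolymer:
            return bc
    raise ExhaustionError("could not draw a barcode with the requested runs")


def design_probeset(
    gene_id: str,
    transcript: str,
    transcriptome: Mapping[str, str],
    *,
    n_odns: int = 48,
    tile_length: int = 30,
    min_gap: int = 2,
    docking_length: int = 46,
    k: int = 15,
    barcode: str | None = None,
    barcode_length: int = 20,
    fluorophore: str = "Cy3",
    seed: int = 0,
) -> ProbeSet:
    """Design a complete probe set for one transcript.

    Tiles the transcript, generates one shared docking sequence screened
    against ``transcriptome`` (which may include the target itself), and
    derives the padlock and detection oligo from a (given or random)
    barcode. The report records per-ODN GC and Tm of the complement arms
    and the docking orthogonality parameters.
    """
    tiles = tile_target(
        transcript, n_odns, tile_length=tile_length, min_gap=min_gap
    )
    dock = generate_docking(
        transcriptome, length=docking_length, k=k, seed=seed
    )
    odns = tuple(
        assemble_odn(
            comp, dock, target_start=s, target_end=e,
            complement_length=tile_length, docking_length=docking_length,
        )
        for comp, s, e in tiles
    )
    if barcode is None:
        barcode = random_barcode(barcode_length, seed=seed + 1)
    padlock = design_padlock(dock, barcode)
    detection = DetectionOligo(sequence=barcode, fluorophore=fluorophore)
    gcs = [gc_fraction(o.complement_region) for o in odns]
    tms = [float(MeltingTemp.Tm_NN(Seq(o.complement_region))) for o in odns]
    report = dict(
        n_odns=len(odns),
        gc_min=float(min(gcs)),
        gc_max=float(max(gcs)),
        tm_min=min(tms),
        tm_max=max(tms),
        orthogonality_k=k,
    )
    return ProbeSet(
        gene_id=gene_id, odns=odns, padlock=padlock,
        detection_oligo=detection, report=report,
    )


def validate_probeset(
    probeset: ProbeSet, transcriptome: Mapping[str, str], *, k: int = 15
) -> dict[str, bool]:
    """Re-check every structural and orthogonality invariant of a probe set.

    Checks (all reported, none raising):

    * ``architecture`` — every ODN is complement + TTTT + docking with the
      expected segment lengths and a pure ACGT alphabet;
    * ``shared_docking`` — all ODNs share one docking sequence;
    * ``complement_maps`` — each complement arm reverse-complements onto
      its stated coordinates of the target transcript
      (``transcriptome[gene_id]``);
    * ``complement_unique`` — each targeted window occurs exactly once
      across the whole transcriptome (no other perfect hit);
    * ``docking_orthogonal`` — the docking sequence shares no k-mer with
      the transcriptome on either strand (brute-force k-mer intersection);
    * ``padlock_junction`` — 3′ arm + 5′ arm reverse-complements to the
      docking sequence exactly;
    * ``detection_matches_barcode`` — detection oligo equals the barcode.
    """
    target = transcriptome.get(probeset.gene_id)
    norm_tx = {gid: _normalize(s) for gid, s in transcriptome.items()}

    docking = probeset.odns[0].docking_region if probeset.odns else ""
    architecture = bool(probeset.odns) and all(
        o.hinge == HINGE
        and set(o.sequence) <= _ALPHABET
        and o.sequence == o.complement_region + HINGE + o.docking_region
        for o in probeset.odns
    )
    shared_docking = all(o.docking_region == docking for o in probeset.odns)

    complement_maps = target is not None and all(
        _revcomp(o.complement_region)
        == _normalize(target)[o.target_start : o.target_end]
        for o in probeset.odns
    )

    def _occurrences(window: str) -> int:
        n = 0
        for s in norm_tx.values():
            start = 0
            while (idx := s.find(window, start)) != -1:
                n += 1
                start = idx + 1
        return n

    complement_unique = all(
        _occurrences(_revcomp(o.complement_region)) == 1 for o in probeset.odns
    )

    forbidden: set[str] = set()
    for s in norm_tx.values():
        forbidden.update(_kmers(s, k))
        forbidden.update(_kmers(_revcomp(s), k))
    docking_orthogonal = bool(docking) and not any(
        m in forbidden for m in _kmers(docking, k)
    )

    pl = probeset.padlock
    padlock_junction = _revcomp(pl.arm_3prime + pl.arm_5prime) == docking
    detection_matches_barcode = probeset.detection_oligo.sequence == pl.barcode

    return dict(
        architecture=architecture,
        shared_docking=shared_docking,
        complement_maps=complement_maps,
        complement_unique=complement_unique,
        docking_orthogonal=docking_orthogonal,
        padlock_junction=padlock_junction,
        detection_matches_barcode=detection_matches_barcode,
    )
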