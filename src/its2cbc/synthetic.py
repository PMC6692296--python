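"""Synthetic ITS-2-like structure families with planted, manifest-recorded events.

The generator emulates the study design every pipeline stage is tested
against: families of strains sharing a four-helix ITS-2-like architecture
(helices emerging from an unpaired backbone, conserved stems, a designated
variable region), split into groups whose ancestors differ by planted
compensatory (CBC), hemi-compensatory (HCBC), neutral and indel events,
while strains within a group carry only neutral noise. Every edit is
recorded in a manifest together with the pairwise CBC/HCBC counts and the
species partition it implies, so recovery by the analysis pipeline can be
checked exactly. A companion fixture builder produces SSU-like alignments
with an exact number of variable columns and an optional intron-like
insertion block restricted to carrier strains.

All randomness flows through one :class:`numpy.random.Generator` seeded from
the spec; a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .events import classify_change, classify_pair_state
from .io import AnnotatedStructure, Region, SequenceRecord, StructureError

__all__ = [
    "HelixSpec",
    "IndelSpec",
    "EventSpec",
    "FamilySpec",
    "Manifest",
    "SSUManifest",
    "make_template",
    "mutate_with_events",
    "make_family",
    "make_ssu_fixture",
]

_PC_PAIRS: tuple[tuple[str, str], ...] = (
    ("A", "U"),
    ("U", "A"),
    ("G", "C"),
    ("C", "G"),
    ("G", "U"),
    ("U", "G"),
)
# stems are mostly Watson–Crick with occasional wobbles, like real helices
_PC_WEIGHTS = np.array([0.22, 0.22, 0.22, 0.22, 0.06, 0.06])
_BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class HelixSpec:
    """One hairpin: ``stem`` base pairs closing a ``loop`` of unpaired bases."""

    stem: int
    loop: int

    def __post_init__(self) -> None:
        if self.stem < 1 or self.loop < 1:
            raise StructureError("stem and loop lengths must be >= 1")


@dataclass(frozen=True)
class IndelSpec:
    """An insertion or deletion of ``length`` bases inside the variable region."""

    length: int
    kind: str = "insertion"  # or "deletion"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise StructureError("indel length must be >= 1")
        if self.kind not in ("insertion", "deletion"):
            raise StructureError(f"unknown indel kind {self.kind!r}")


@dataclass(frozen=True)
class EventSpec:
    """Counts of planted events separating one group ancestor from the template."""

    n_cbc: int = 2
    n_hcbc: int = 2
    n_neutral: int = 2
    indels: tuple[IndelSpec, ...] = ()


@dataclass(frozen=True)
class FamilySpec:
    """Study-design parameters for one synthetic family.

    Defaults mirror the analysed strain set: six strains in two groups of
    three, a four-helix ITS-2-like molecule, and two CBCs plus two HCBCs
    separating the group ancestors.
    """

    n_groups: int = 2
    strains_per_group: int = 3
    helices: tuple[HelixSpec, ...] = (
        HelixSpec(7, 4),
        HelixSpec(6, 4),
        HelixSpec(10, 6),
        HelixSpec(5, 4),
    )
    spacer: int = 4
    variable_region: int = 12
    between_events: EventSpec = EventSpec()
    within_neutral: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.strains_per_group < 1:
            raise StructureError("need at least one group and one strain per group")
        if not self.helices:
            raise StructureError("need at least one helix")
        if self.spacer < 1 or self.variable_region < 0:
            raise StructureError("invalid spacer/variable-region lengths")


def _pair_bases(rng: np.random.Generator) -> tuple[str, str]:
    idx = rng.choice(len(_PC_PAIRS), p=_PC_WEIGHTS)
    return _PC_PAIRS[idx]


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=n)]


def make_template(spec: FamilySpec, rng: np.random.Generator | None = None) -> AnnotatedStructure:
    """Build the family ancestor: nested helices, spacers and a variable region.

    Layout (5′→3′): spacer, then each helix as 5′ stem/loop/3′ stem followed
    by a spacer, with the unpaired variable region inserted before the last
    helix. Stems draw pairing-capable pairs (mostly Watson–Crick); loops and
    spacers draw uniform bases. Deterministic under the spec's seed.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    bases: list[str] = []
    pairs: set[tuple[int, int]] = set()
    regions: list[Region] = []

    bases.extend(_random_bases(rng, spec.spacer))
    var_before = len(spec.helices) - 1  # variable region sits before the last helix
    for h_idx, h in enumerate(spec.helices):
        if h_idx == var_before and spec.variable_region:
            start = len(bases) + 1
            bases.extend(_random_bases(rng, spec.variable_region))
            regions.append(Region("variable", start, len(bases)))
            bases.extend(_random_bases(rng, spec.spacer))
        h_start = len(bases) + 1
        five: list[str] = []
        three: list[str] = []
        for _ in range(h.stem):
            n5, n3 = _pair_bases(rng)
            five.append(n5)
            three.append(n3)
        bases.extend(five)
        bases.extend(_random_bases(rng, h.loop))
        for k in range(h.stem):
            # 3′ side mirrors the 5′ side: innermost pair closes the loop
            bases.append(three[h.stem - 1 - k])
        h_end = len(bases)
        for k in range(h.stem):
            pairs.add((h_start + k, h_end - k))
        regions.append(Region(f"helix{h_idx + 1}", h_start, h_end))
        bases.extend(_random_bases(rng, spec.spacer))
    regions.append(Region("its2", 1, len(bases)))

    rec = SequenceRecord(id="template", seq="".join(bases), source="synthetic")
    return AnnotatedStructure(record=rec, pairs=frozenset(pairs), regions=tuple(regions))


# ---------------------------------------------------------------------------
# Planting events


@dataclass(frozen=True)
class PlantedEvent:
    """One recorded edit, in template (ancestor) coordinates."""

    kind: str  # CBC | HCBC | neutral | insertion | deletion
    position: int  # 5′ position of the pair, substitution site, or indel anchor
    partner: int | None = None  # 3′ position for pair events
    before: str = ""
    after: str = ""

    def to_json(self) -> dict:
        return asdict(self)


def _hemi_candidates(n5: str, n3: str) -> list[tuple[str, str]]:
    return [
        (x, y)
        for x, y in _PC_PAIRS
        if (x == n5) != (y == n3) and (x, y) != (n5, n3)
    ]


def _cbc_candidates(n5: str, n3: str) -> list[tuple[str, str]]:
    return [(x, y) for x, y in _PC_PAIRS if x != n5 and y != n3]


def mutate_with_events(
    template: AnnotatedStructure,
    events: EventSpec,
    rng: np.random.Generator,
    exclude_pairs: set[tuple[int, int]] | None = None,
    exclude_positions: set[int] | None = None,
    strain_id: str = "derived",
) -> tuple[AnnotatedStructure, list[PlantedEvent]]:
    """Derive a structure from the template by planting the requested events.

    CBC events replace a base pair with one differing on both sides while
    remaining pairing-capable; HCBC events change exactly one side; neutral
    substitutions hit unpaired columns; indels act inside the variable
    region. No two events touch the same pair or column (``exclude_*``
    extends the exclusion across calls), so downstream counts are exactly
    the planted counts.
    """
    exclude_pairs = set(exclude_pairs or ())
    exclude_positions = set(exclude_positions or ())
    bases = list(template.seq)
    planted: list[PlantedEvent] = []

    free_pairs = [p for p in sorted(template.pairs) if p not in exclude_pairs]
    n_pair_events = events.n_cbc + events.n_hcbc
    if n_pair_events > len(free_pairs):
        raise StructureError(
            f"cannot plant {n_pair_events} pair events on {len(free_pairs)} free pairs"
        )
    chosen = rng.choice(len(free_pairs), size=n_pair_events, replace=False)
    chosen_pairs = [free_pairs[int(c)] for c in chosen]
    for idx, (i, j) in enumerate(chosen_pairs):
        n5, n3 = bases[i - 1], bases[j - 1]
        if idx < events.n_cbc:
            cands = _cbc_candidates(n5, n3)
            kind = "CBC"
        else:
            cands = _hemi_candidates(n5, n3)
            kind = "HCBC"
        x, y = cands[int(rng.integers(0, len(cands)))]
        planted.append(
            PlantedEvent(
                kind=kind, position=i, partner=j, before=f"{n5}{n3}", after=f"{x}{y}"
            )
        )
        bases[i - 1], bases[j - 1] = x, y
        exclude_pairs.add((i, j))

    paired_positions = {i for ij in template.pairs for i in ij}
    free_unpaired = [
        p
        for p in range(1, len(template) + 1)
        if p not in paired_positions and p not in exclude_positions
    ]
    if events.n_neutral > len(free_unpaired):
        raise StructureError(
            f"cannot plant {events.n_neutral} neutral substitutions on "
            f"{len(free_unpaired)} free unpaired columns"
        )
    chosen = rng.choice(len(free_unpaired), size=events.n_neutral, replace=False)
    for c in chosen:
        p = free_unpaired[int(c)]
        old = bases[p - 1]
        new = old
        while new == old:
            new = _BASES[int(rng.integers(0, 4))]
        planted.append(PlantedEvent(kind="neutral", position=p, before=old, after=new))
        bases[p - 1] = new
        exclude_positions.add(p)

    pairs = set(template.pairs)
    regions = list(template.regions)
    for indel in events.indels:
        bases, pairs, regions, ev = _apply_indel(
            template, bases, pairs, regions, indel, rng
        )
        planted.append(ev)

    rec = SequenceRecord(id=strain_id, seq="".join(bases), source="synthetic")
    derived = AnnotatedStructure(
        record=rec, pairs=frozenset(pairs), regions=tuple(regions)
    )
    return derived, planted


def _apply_indel(
    template: AnnotatedStructure,
    bases: list[str],
    pairs: set[tuple[int, int]],
    regions: list[Region],
    indel: IndelSpec,
    rng: np.random.Generator,
) -> tuple[list[str], set[tuple[int, int]], list[Region], PlantedEvent]:
    try:
        var = next(r for r in regions if r.name == "variable")
    except StopIteration:
        raise StructureError("template has no variable region for indel events")
    if indel.kind == "deletion" and indel.length > var.width:
        raise StructureError("deletion longer than the variable region")
    if indel.kind == "insertion":
        anchor = int(rng.integers(var.start, var.end + 1))  # insert after anchor
        inserted = _random_bases(rng, indel.length)
        bases = bases[:anchor] + inserted + bases[anchor:]
        shift = indel.length
        ev = PlantedEvent(
            kind="insertion", position=anchor, after="".join(inserted)
        )
    else:
        start = int(rng.integers(var.start, var.end - indel.length + 2))
        removed = bases[start - 1 : start - 1 + indel.length]
        bases = bases[: start - 1] + bases[start - 1 + indel.length :]
        anchor = start - 1
        shift = -indel.length
        ev = PlantedEvent(kind="deletion", position=start, before="".join(removed))

    def move(p: int) -> int:
        return p + shift if p > anchor else p

    pairs = {(move(i), move(j)) for i, j in pairs}
    regions = [
        Region(r.name, move(r.start) if r.start > anchor else r.start, move(r.end))
        if r.end > anchor
        else r
        for r in regions
    ]
    return bases, pairs, regions, ev


# ---------------------------------------------------------------------------
# Families


@dataclass
class Manifest:
    """Ground truth for one generated family.

    ``expected_cbc``/``expected_hcbc`` are nested dicts keyed by strain id;
    ``expected_groups`` is the planted species partition. Round-trips
    through JSON.
    """

    seed: int
    strain_ids: list[str]
    groups: list[list[str]]
    events: dict[str, list[PlantedEvent]] = field(default_factory=dict)
    expected_cbc: dict[str, dict[str, int]] = field(default_factory=dict)
    expected_hcbc: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def expected_groups(self) -> list[list[str]]:
        return self.groups

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "strain_ids": self.strain_ids,
            "groups": self.groups,
            "events": {
                sid: [e.to_json() for e in evs] for sid, evs in self.events.items()
            },
            "expected_cbc": self.expected_cbc,
            "expected_hcbc": self.expected_hcbc,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "Manifest":
        return cls(
            seed=doc["seed"],
            strain_ids=list(doc["strain_ids"]),
            groups=[list(g) for g in doc["groups"]],
            events={
                sid: [PlantedEvent(**e) for e in evs]
                for sid, evs in doc["events"].items()
            },
            expected_cbc={k: dict(v) for k, v in doc["expected_cbc"].items()},
            expected_hcbc={k: dict(v) for k, v in doc["expected_hcbc"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        return cls.from_json(json.loads(Path(path).read_text()))


def _pair_state_dict(
    template: AnnotatedStructure, struct_bases: dict[int, str]
) -> dict[tuple[int, int], tuple[str, str]]:
    return {
        (i, j): (struct_bases[i], struct_bases[j]) for i, j in sorted(template.pairs)
    }


def make_family(spec: FamilySpec) -> tuple[list[AnnotatedStructure], Manifest]:
    """Generate a strain family with planted group structure.

    The first group's ancestor is the template itself; each further group's
    ancestor carries its own planted between-group events on pairs no other
    group touched. Strains within a group add only neutral substitutions at
    unpaired columns, so within-group CBC counts are zero by construction.
    Expected pairwise CBC/HCBC counts are derived from the per-pair states
    of the (pre-indel) ancestors by the definitional classification rules.
    """
    rng = np.random.default_rng(spec.seed)
    template = make_template(spec, rng)

    used_pairs: set[tuple[int, int]] = set()
    used_positions: set[int] = set()
    ancestors: list[tuple[AnnotatedStructure, list[PlantedEvent]]] = [(template, [])]
    for _ in range(1, spec.n_groups):
        anc, planted = mutate_with_events(
            template,
            spec.between_events,
            rng,
            exclude_pairs=used_pairs,
            exclude_positions=used_positions,
            strain_id="ancestor",
        )
        ancestors.append((anc, planted))

    structs: list[AnnotatedStructure] = []
    manifest = Manifest(seed=spec.seed, strain_ids=[], groups=[])
    # per-strain substituted base at each *template* position, for expectations
    anc_pair_states: dict[str, dict[tuple[int, int], tuple[str, str]]] = {}
    k = 0
    for g, (anc, planted) in enumerate(ancestors):
        group_ids: list[str] = []
        for _ in range(spec.strains_per_group):
            k += 1
            sid = f"s{k}"
            noise = EventSpec(n_cbc=0, n_hcbc=0, n_neutral=spec.within_neutral)
            # plant strain noise relative to the group ancestor; pair columns
            # untouched so the ancestor's pair states carry over verbatim
            strain, strain_events = _add_neutral_noise(anc, noise, rng, sid)
            structs.append(strain)
            group_ids.append(sid)
            manifest.strain_ids.append(sid)
            manifest.events[sid] = planted + strain_events
            # map ancestor pair positions back to template coordinates: indels
            # only ever move whole pairs, recorded via the ancestor's pair order
            anc_pair_states[sid] = {
                tp: (strain.record.base(ap[0]), strain.record.base(ap[1]))
                for tp, ap in zip(sorted(template.pairs), sorted(anc.pairs))
            }
        manifest.groups.append(group_ids)

    for sid in manifest.strain_ids:
        manifest.expected_cbc[sid] = {}
        manifest.expected_hcbc[sid] = {}
    ids = manifest.strain_ids
    for i, a in enumerate(ids):
        for b in ids[i:]:
            if a == b:
                n_cbc = n_hcbc = 0
            else:
                n_cbc = n_hcbc = 0
                for tp in sorted(template.pairs):
                    sa = classify_pair_state(*anc_pair_states[a][tp])
                    sb = classify_pair_state(*anc_pair_states[b][tp])
                    klass = classify_change(sa, sb).value
                    if klass == "CBC":
                        n_cbc += 1
                    elif klass == "HCBC":
                        n_hcbc += 1
            manifest.expected_cbc[a][b] = manifest.expected_cbc.setdefault(b, {})[a] = n_cbc
            manifest.expected_hcbc[a][b] = manifest.expected_hcbc.setdefault(b, {})[a] = n_hcbc
    return structs, manifest


def _add_neutral_noise(
    ancestor: AnnotatedStructure,
    noise: EventSpec,
    rng: np.random.Generator,
    strain_id: str,
) -> tuple[AnnotatedStructure, list[PlantedEvent]]:
    bases = list(ancestor.seq)
    paired = {i for ij in ancestor.pairs for i in ij}
    free = [p for p in range(1, len(ancestor) + 1) if p not in paired]
    if noise.n_neutral > len(free):
        raise StructureError("not enough unpaired columns for within-group noise")
    chosen = rng.choice(len(free), size=noise.n_neutral, replace=False)
    planted: list[PlantedEvent] = []
    for c in chosen:
        p = free[int(c)]
        old = bases[p - 1]
        new = old
        while new == old:
            new = _BASES[int(rng.integers(0, 4))]
        bases[p - 1] = new
        planted.append(PlantedEvent(kind="neutral", position=p, before=old, after=new))
    rec = SequenceRecord(id=strain_id, seq="".join(bases), source="synthetic")
    return (
        AnnotatedStructure(record=rec, pairs=ancestor.pairs, regions=ancestor.regions),
        planted,
    )


# ---------------------------------------------------------------------------
# SSU-like alignment fixture


@dataclass
class SSUManifest:
    """Ground truth for one SSU-like alignment fixture."""

    seed: int
    strain_ids: list[str]
    variable_positions: list[int]  # 1-based alignment columns
    intron_start: int | None = None  # 1-based first alignment column of the block
    intron_length: int = 0
    intron_carriers: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2, sort_keys=True))


def make_ssu_fixture(
    n_strains: int = 6,
    n_variable_positions: int = 15,
    intron: tuple[tuple[str, ...], int, int] | None = (("s3", "s6"), 400, 516),
    length: int = 1800,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SSUManifest]:
    """Build an SSU-like alignment with exact planted variability.

    Exactly ``n_variable_positions`` columns vary among the strains (each
    variable column gives a proper, non-empty strain subset an alternative
    residue); all other non-intron columns are invariant. ``intron`` is
    ``(carriers, length, position)``: an identical intron-like sequence is
    inserted after sequence position ``position`` in the carrier rows and
    gapped in all others, emulating a group I intron shared in position but
    restricted to carrier strains.
    """
    rng = np.random.default_rng(seed)
    if n_strains < 2:
        raise StructureError("need at least two strains")
    if n_variable_positions > length:
        raise StructureError("more variable positions than sequence columns")
    ids = [f"s{i + 1}" for i in range(n_strains)]
    base = _random_bases(rng, length)
    var_pos = sorted(int(p) + 1 for p in rng.choice(length, n_variable_positions, replace=False))

    rows: dict[str, list[str]] = {sid: list(base) for sid in ids}
    for p in var_pos:
        n_alt = int(rng.integers(1, n_strains))  # proper, non-empty subset
        alt_strains = [ids[int(i)] for i in rng.choice(n_strains, n_alt, replace=False)]
        old = base[p - 1]
        new = old
        while new == old:
            new = _BASES[int(rng.integers(0, 4))]
        for sid in alt_strains:
            rows[sid][p - 1] = new

    manifest = SSUManifest(seed=seed, strain_ids=ids, variable_positions=list(var_pos))
    if intron is not None:
        carriers, ilen, pos = intron
        carriers = tuple(carriers)
        if not set(carriers) <= set(ids) or not carriers or set(carriers) == set(ids):
            raise StructureError("intron carriers must be a proper non-empty subset")
        if not (0 <= pos <= length):
            raise StructureError("intron position outside the sequence")
        intron_seq = _random_bases(rng, ilen)
        for sid in ids:
            block = intron_seq if sid in carriers else ["-"] * ilen
            rows[sid] = rows[sid][:pos] + block + rows[sid][pos:]
        manifest.intron_start = pos + 1
        manifest.intron_length = ilen
        manifest.intron_carriers = sorted(carriers)
        manifest.variable_positions = [p if p <= pos else p + ilen for p in var_pos]

    records = [
        SequenceRecord(id=sid, seq="".join(rows[sid]), source="synthetic")
        for sid in ids
    ]
    return records, manifest
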