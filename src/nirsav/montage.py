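"""Probe montage: 46 source-detector channels with hemisphere and region labels.

The headgear modelled here is a bilateral fronto-temporal array of 46
measurement channels (2 cm source-detector separation), 23 per hemisphere.
Two anatomical regions of interest are tagged on individual channels: the
inferior frontal region and the superior temporal region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

N_CHANNELS = 46

#: Channel ids of the two regions of interest.  Reconstructed from the
#: published probe diagram (the boxed channel sets); the left/right split by
#: channel id (1-23 left, 24-46 right) is a versioned convention of this
#: package, consistent with the region members below.
INFERIOR_FRONTAL = frozenset({3, 4, 24, 26})
SUPERIOR_TEMPORAL = frozenset({5, 15, 27, 28, 29, 31})


@dataclass(frozen=True)
class ChannelDef:
    """One measurement channel (a source-detector pair)."""

    id: int
    source_id: int
    detector_id: int
    hemisphere: str  # "left" | "right"
    region: str  # "inferior_frontal" | "superior_temporal" | "other"
    neighbors: frozenset[int] = field(default_factory=frozenset)
    separation_cm: float = 2.0


@dataclass(frozen=True)
class Montage:
    """A validated set of 46 channels.

    Invariants (enforced by :meth:`validate`): exactly 46 channels with ids
    1..46, symmetric adjacency, every channel labelled with a hemisphere,
    disjoint inferior-frontal / superior-temporal sets, positive separations.
    """

    channels: tuple[ChannelDef, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.id for c in self.channels]
        if sorted(ids) != list(range(1, N_CHANNELS + 1)):
            raise ValueError(
                f"montage must contain exactly {N_CHANNELS} channels with ids "
                f"1..{N_CHANNELS}; got {len(ids)} ids"
            )
        by_id = {c.id: c for c in self.channels}
        for c in self.channels:
            if c.hemisphere not in ("left", "right"):
                raise ValueError(f"channel {c.id}: bad hemisphere {c.hemisphere!r}")
            if c.region not in ("inferior_frontal", "superior_temporal", "other"):
                raise ValueError(f"channel {c.id}: bad region {c.region!r}")
            if c.separation_cm <= 0:
                raise ValueError(f"channel {c.id}: separation must be > 0")
            for n in c.neighbors:
                if n not in by_id:
                    raise ValueError(f"channel {c.id}: unknown neighbor {n}")
                if c.id not in by_id[n].neighbors:
                    raise ValueError(f"adjacency not symmetric: {c.id} -> {n}")
        inf = {c.id for c in self.channels if c.region == "inferior_frontal"}
        sup = {c.id for c in self.channels if c.region == "superior_temporal"}
        if inf & sup:
            raise ValueError("inferior-frontal and superior-temporal sets overlap")

    # -- convenience accessors -------------------------------------------------
    def channel(self, cid: int) -> ChannelDef:
        return next(c for c in self.channels if c.id == cid)

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.channels]

    def hemisphere_ids(self, hemisphere: str) -> list[int]:
        if hemisphere not in ("left", "right"):
            raise ValueError(f"bad hemisphere {hemisphere!r}")
        return [c.id for c in self.channels if c.hemisphere == hemisphere]

    def region_ids(self, region: str) -> list[int]:
        return [c.id for c in self.channels if c.region == region]

    def subset_ids(self, subset: str) -> list[int]:
        """Channel ids for a decoding subset tag: 'all' | 'left' | 'right'."""
        if subset == "all":
            return self.ids
        return self.hemisphere_ids(subset)

    def separations(self) -> dict[int, float]:
        return {c.id: c.separation_cm for c in self.channels}

    # -- (de)serialisation -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [
            {**asdict(c), "neighbors": sorted(c.neighbors)} for c in self.channels
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        chans = tuple(
            ChannelDef(
                id=int(d["id"]),
                source_id=int(d["source_id"]),
                detector_id=int(d["detector_id"]),
                hemisphere=d["hemisphere"],
                region=d["region"],
                neighbors=frozenset(int(n) for n in d["neighbors"]),
                separation_cm=float(d["separation_cm"]),
            )
            for d in payload
        )
        return cls(chans)


def _chain_neighbors(ids: Iterable[int]) -> dict[int, set[int]]:
    ids = sorted(ids)
    nb: dict[int, set[int]] = {i: set() for i in ids}
    for a, b in zip(ids, ids[1:]):
        nb[a].add(b)
        nb[b].add(a)
    return nb


def default_montage(separation_cm: float = 2.0) -> Montage:
    """The default 46-channel fixture.

    Synthetic reconstruction: hemisphere by channel id (1-23 left, 24-46
    right), regions per :data:`INFERIOR_FRONTAL` / :data:`SUPERIOR_TEMPORAL`,
    and a within-hemisphere chain adjacency.  Source/detector ids follow a
    simple pairing scheme and do not reproduce the physical array wiring.
    """
    neighbors = {}
    neighbors.update(_chain_neighbors(range(1, 24)))
    neighbors.update(_chain_neighbors(range(24, 47)))
    chans = []
    for cid in range(1, N_CHANNELS + 1):
        hemi = "left" if cid <= 23 else "right"
        if cid in INFERIOR_FRONTAL:
            region = "inferior_frontal"
        elif cid in SUPERIOR_TEMPORAL:
            region = "superior_temporal"
        else:
            region = "other"
        chans.append(
            ChannelDef(
                id=cid,
                source_id=(cid - 1) // 2 + 1,
                detector_id=(cid - 1) // 2 + 1 + ((cid - 1) % 2),
                hemisphere=hemi,
                region=region,
                neighbors=frozenset(neighbors[cid]),
                separation_cm=separation_cm,
            )
        )
    return Montage(tuple(chans))
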