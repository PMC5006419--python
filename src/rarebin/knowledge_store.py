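"""File-backed biological knowledge: regions and groups that define bin boundaries.

A *region* is any named genomic segment (gene, conserved element, custom
interval) given as a BED-style half-open interval.  A *group* is a named set of
regions and/or child groups (a pathway, protein family, interaction cluster).
Together they form the two knowledge levels on which variants are collapsed.

Coordinates are 0-based half-open throughout (BED convention); VCF positions
are converted on ingest elsewhere.  Strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "Region",
    "RegionSet",
    "Group",
    "GroupSet",
    "KnowledgeBase",
    "KnowledgeError",
    "load_region_file",
    "load_group_file",
    "load_knowledge",
    "write_region_file",
    "regions_at",
    "expand_group",
]


class KnowledgeError(ValueError):
    """Malformed or inconsistent knowledge input."""


@dataclass(frozen=True)
class Region:
    """A named genomic interval, 0-based half-open ``[start, stop)``."""

    region_id: str
    name: str
    chrom: str
    start: int
    stop: int
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise KnowledgeError(f"region {self.region_id!r}: empty chromosome")
        if self.start >= self.stop:
            raise KnowledgeError(
                f"region {self.region_id!r}: start {self.start} >= stop {self.stop}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.stop


class RegionSet:
    """Regions indexed by id and by per-chromosome interval tree."""

    def __init__(self, regions: Iterable[Region] = ()) -> None:
        self._by_id: dict[str, Region] = {}
        self._trees: dict[str, IntervalTree] = {}
        for region in regions:
            self.add(region)

    def add(self, region: Region) -> None:
        if region.region_id in self._by_id:
            raise KnowledgeError(f"duplicate region id {region.region_id!r}")
        self._by_id[region.region_id] = region
        self._trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.stop, region.region_id
        )

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Region]:
        return iter(self._by_id.values())

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __getitem__(self, region_id: str) -> Region:
        return self._by_id[region_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._by_id == other._by_id

    def at(self, chrom: str, pos: int) -> list[Region]:
        """All regions with ``start <= pos < stop`` on ``chrom``, id-sorted."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(pos))
        return [self._by_id[rid] for rid in hits]


@dataclass
class Group:
    """A named collection of regions and child groups (pathway, family, ...)."""

    group_id: str
    source: str = ""
    member_region_ids: set[str] = field(default_factory=set)
    member_group_ids: set[str] = field(default_factory=set)


class GroupSet:
    def __init__(self, groups: Iterable[Group] = ()) -> None:
        self._by_id: dict[str, Group] = {}
        for g in groups:
            self.add(g)

    def add(self, group: Group) -> None:
        if group.group_id in self._by_id:
            raise KnowledgeError(f"duplicate group id {group.group_id!r}")
        self._by_id[group.group_id] = group

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Group]:
        return iter(self._by_id.values())

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._by_id

    def __getitem__(self, group_id: str) -> Group:
        return self._by_id[group_id]


@dataclass
class KnowledgeBase:
    """Loaded regions + groups + the source tags they came from."""

    regions: RegionSet
    groups: GroupSet = field(default_factory=GroupSet)

    @property
    def sources(self) -> set[str]:
        tags = {r.source for r in self.regions if r.source}
        tags |= {g.source for g in self.groups if g.source}
        return tags


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def load_region_file(path: str | Path, source_tag: str = "") -> RegionSet:
    """Parse a BED-like region file: ``chrom  start  stop  name`` per line.

    Coordinates are taken as 0-based half-open.  The region name doubles as
    its id, so names must be unique within a file.  ``#`` comments and blank
    lines are skipped.  Raises :class:`KnowledgeError` naming the offending
    line on any malformed input.
    """
    regions = RegionSet()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise KnowledgeError(
                f"{path}:{lineno}: expected 'chrom start stop name', got {len(fields)} fields"
            )
        chrom, start_s, stop_s, name = fields[:4]
        try:
            start, stop = int(start_s), int(stop_s)
        except ValueError as exc:
            raise KnowledgeError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start >= stop:
            raise KnowledgeError(f"{path}:{lineno}: start {start} >= stop {stop}")
        try:
            regions.add(Region(name, name, chrom, start, stop, source_tag))
        except KnowledgeError as exc:
            raise KnowledgeError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_region_file(regions: RegionSet, path: str | Path) -> None:
    """Serialize back to the region-file dialect (round-trips exactly)."""
    with open(path, "w") as handle:
        for region in sorted(regions, key=lambda r: r.region_id):
            handle.write(f"{region.chrom}\t{region.start}\t{region.stop}\t{region.region_id}\n")


def _find_cycle(groups: GroupSet) -> list[str] | None:
    """Return one directed cycle among group->child edges, if any."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {g.group_id: WHITE for g in groups}
    stack: list[str] = []

    def dfs(node: str) -> list[str] | None:
        color[node] = GREY
        stack.append(node)
        for child in sorted(groups[node].member_group_ids):
            if child not in color:
                continue
            if color[child] == GREY:
                return stack[stack.index(child):] + [child]
            if color[child] == WHITE:
                found = dfs(child)
                if found:
                    return found
        stack.pop()
        color[node] = BLACK
        return None

    for gid in sorted(color):
        if color[gid] == WHITE:
            found = dfs(gid)
            if found:
                return found
    return None


def load_group_file(path: str | Path, regions: RegionSet) -> GroupSet:
    """Parse group memberships: ``group_id  source  member_type  member_id``.

    ``member_type`` is ``region`` or ``group``; one membership per line.
    Every region member must resolve in ``regions``; group members must be
    defined somewhere in the same file; membership cycles are rejected with
    the cycle spelled out.
    """
    groups = GroupSet()
    pending: list[tuple[int, str, str]] = []  # (lineno, group_id, child_group_id)
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise KnowledgeError(
                f"{path}:{lineno}: expected 'group_id source member_type member_id'"
            )
        gid, source, mtype, mid = fields[:4]
        if gid not in groups:
            groups.add(Group(gid, source))
        group = groups[gid]
        if mtype == "region":
            group.member_region_ids.add(mid)
        elif mtype == "group":
            group.member_group_ids.add(mid)
            pending.append((lineno, gid, mid))
        else:
            raise KnowledgeError(f"{path}:{lineno}: member_type must be region|group")

    missing = sorted(
        {mid for g in groups for mid in g.member_region_ids if mid not in regions}
    )
    if missing:
        raise KnowledgeError(f"{path}: unknown region members: {', '.join(missing)}")
    unknown_groups = sorted({mid for _, _, mid in pending if mid not in groups})
    if unknown_groups:
        raise KnowledgeError(f"{path}: unknown group members: {', '.join(unknown_groups)}")
    cycle = _find_cycle(groups)
    if cycle:
        raise KnowledgeError(f"{path}: group membership cycle: {' -> '.join(cycle)}")
    return groups


def load_knowledge(
    region_path: str | Path,
    group_path: str | Path | None = None,
    source_tag: str = "custom",
) -> KnowledgeBase:
    regions = load_region_file(region_path, source_tag)
    groups = load_group_file(group_path, regions) if group_path else GroupSet()
    return KnowledgeBase(regions=regions, groups=groups)


def regions_at(kb: KnowledgeBase, chrom: str, pos: int) -> list[Region]:
    """Regions containing position ``pos`` on ``chrom``, in region_id order."""
    return kb.regions.at(chrom, pos)


def expand_group(kb: KnowledgeBase, group_id: str) -> set[str]:
    """Transitive closure of a group's region membership over nested groups."""
    if group_id not in kb.groups:
        raise KnowledgeError(f"unknown group id {group_id!r}")
    seen_groups: set[str] = set()
    regions: set[str] = set()
    frontier = [group_id]
    while frontier:
        gid = frontier.pop()
        if gid in seen_groups:
            continue
        seen_groups.add(gid)
        group = kb.groups[gid]
        regions |= group.member_region_ids
        frontier.extend(group.member_group_ids)
    return regions
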