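"""Assembly of the five-component peptide search database.

Components: Fusion and Splicing (merged junction peptides with junction
metadata in the FASTA header), Annotated (known proteome, whole
proteins), Contaminated (contaminant proteins), and Reversal
(character-reversed decoys of all forward entries, for target-decoy FDR
control). Duplicate junction peptides are merged into one entry per
component with their provenance lists concatenated; a sequence arising
both as fusion and as splicing keeps one entry in each component, and
the conflict is resolved at identification time by category precedence.

Junction entry headers are pipe-delimited::

    >Fusion|fus_000001|genes=A:B|exons=e1:e7|frame=0|junction_aa=4|straddle=0|n_prov=2

Annotated/Contaminated/Reversal entries use the short form
``>{component}|{entry_id}``; decoy ids carry a ``rev_`` prefix.
"""

from __future__ import annotations

import collections
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import GeneModel, GenePair
from .insilico_digest import PeptideRecord, digest_junction
from .junction_builder import (
    enumerate_fusion_junctions,
    enumerate_splicing_junctions,
    translate_junction,
)

__all__ = [
    "COMPONENTS",
    "EntryMeta",
    "DatabaseEntry",
    "DatabaseManifest",
    "PeptideDatabase",
    "merge_entries",
    "proteome_entries",
    "build_decoys",
    "build_database",
    "write_database",
    "read_database",
]

COMPONENTS = ("Fusion", "Splicing", "Annotated", "Contaminated", "Reversal")

DECOY_PREFIX = "rev_"


@dataclass(frozen=True)
class EntryMeta:
    """Junction metadata of a Fusion/Splicing entry."""

    genes: tuple[str, str]
    exons: tuple[str, str]
    frame: int
    junction_left_aa: int
    straddle: bool
    provenance: tuple = ()
    # survives FASTA round trips, where full provenance objects do not
    n_merged: int = 0

    @property
    def n_provenance(self) -> int:
        return len(self.provenance) or self.n_merged


@dataclass(frozen=True)
class DatabaseEntry:
    entry_id: str
    component: str
    sequence: str
    meta: EntryMeta | None = None
    mirror_of: str | None = None  # forward entry id, for Reversal entries

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if not self.sequence:
            raise ValueError(f"entry {self.entry_id}: empty sequence")


@dataclass
class DatabaseManifest:
    """Per-component entry counts plus build parameters and input digests."""

    counts: dict[str, int]
    build_params: dict = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        forward = sum(self.counts.get(c, 0) for c in COMPONENTS[:4])
        if self.counts.get("Reversal", 0) != forward:
            raise ValueError(
                "manifest inconsistent: Reversal count "
                f"{self.counts.get('Reversal', 0)} != forward total {forward}"
            )


def merge_entries(peptides: Sequence[PeptideRecord]) -> list[DatabaseEntry]:
    """Merge junction peptides into one entry per unique sequence per component.

    Entries are ordered and numbered by sequence within each component so
    the assembly is deterministic; the junction metadata of an entry comes
    from its first provenance record (merged records that disagree keep
    their own details in the provenance list).
    """
    comp_of = {"fusion": "Fusion", "splicing": "Splicing"}
    grouped: dict[tuple[str, str], list[PeptideRecord]] = collections.defaultdict(list)
    for pep in peptides:
        if pep.kind not in comp_of:
            raise ValueError(f"not a junction peptide kind: {pep.kind!r}")
        grouped[(comp_of[pep.kind], pep.sequence)].append(pep)

    prefix = {"Fusion": "fus", "Splicing": "spl"}
    counters: dict[str, int] = collections.Counter()
    entries = []
    for comp, seq in sorted(grouped):
        peps = grouped[(comp, seq)]
        counters[comp] += 1
        first = peps[0]
        prov = tuple(p for pep in peps for p in pep.provenance)
        entries.append(
            DatabaseEntry(
                entry_id=f"{prefix[comp]}_{counters[comp]:06d}",
                component=comp,
                sequence=seq,
                meta=EntryMeta(
                    genes=(first.provenance[0].gene_up, first.provenance[0].gene_down),
                    exons=(first.provenance[0].exon_up, first.provenance[0].exon_down),
                    frame=first.provenance[0].frame,
                    junction_left_aa=first.left_aa,
                    straddle=first.straddle_in_peptide,
                    provenance=prov,
                ),
            )
        )
    return entries


def proteome_entries(
    proteins: Mapping[str, str], component: str = "Annotated"
) -> list[DatabaseEntry]:
    """Wrap whole proteins (proteome or contaminants) as database entries."""
    return [
        DatabaseEntry(entry_id=pid, component=component, sequence=proteins[pid])
        for pid in sorted(proteins)
    ]


def build_decoys(entries: Sequence[DatabaseEntry]) -> list[DatabaseEntry]:
    """One character-reversed Reversal entry per forward entry."""
    decoys = []
    for e in entries:
        if e.component == "Reversal":
            raise ValueError("cannot build a decoy of a decoy")
        decoys.append(
            DatabaseEntry(
                entry_id=DECOY_PREFIX + e.entry_id,
                component="Reversal",
                sequence=e.sequence[::-1],
                mirror_of=e.entry_id,
            )
        )
    return decoys


def build_database(
    models: Mapping[str, GeneModel],
    pairs: Sequence[GenePair],
    proteome: Mapping[str, str],
    contaminants: Mapping[str, str],
    *,
    min_len: int = 6,
    max_misc_per_side: int = 1,
) -> tuple[list[DatabaseEntry], DatabaseManifest]:
    """Run the full assembly: enumerate, translate, digest, merge, decoy.

    Splicing junctions are enumerated for every gene referenced by at
    least one pair. Returns the complete entry list (all five components)
    plus a manifest with verified counts.
    """
    junction_peps: list[PeptideRecord] = []
    for pair in pairs:
        for jn in enumerate_fusion_junctions(pair, models):
            for jp in translate_junction(jn):
                junction_peps.extend(
                    digest_junction(jp, max_misc_per_side, min_len)
                )
    paired_genes = sorted({s for p in pairs for s in (p.symbol_a, p.symbol_b)})
    for sym in paired_genes:
        for jn in enumerate_splicing_junctions(models[sym]):
            for jp in translate_junction(jn):
                junction_peps.extend(
                    digest_junction(jp, max_misc_per_side, min_len)
                )

    entries = merge_entries(junction_peps)
    entries += proteome_entries(proteome, "Annotated")
    entries += proteome_entries(contaminants, "Contaminated")
    entries += build_decoys(entries)

    counts = collections.Counter(e.component for e in entries)
    manifest = DatabaseManifest(
        counts={c: counts.get(c, 0) for c in COMPONENTS},
        build_params={
            "min_len": min_len,
            "max_misc_per_side": max_misc_per_side,
            "n_gene_pairs": len(pairs),
            "n_genes": len(paired_genes),
        },
    )
    manifest.validate()
    return entries, manifest


def _header(e: DatabaseEntry) -> str:
    if e.meta is None:
        return f"{e.component}|{e.entry_id}"
    m = e.meta
    return (
        f"{e.component}|{e.entry_id}|genes={m.genes[0]}:{m.genes[1]}"
        f"|exons={m.exons[0]}:{m.exons[1]}|frame={m.frame}"
        f"|junction_aa={m.junction_left_aa}|straddle={int(m.straddle)}"
        f"|n_prov={m.n_provenance}"
    )


def _component_order(e: DatabaseEntry) -> tuple[int, str]:
    return COMPONENTS.index(e.component), e.entry_id


def write_database(
    entries: Sequence[DatabaseEntry],
    manifest: DatabaseManifest,
    path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Write the database FASTA and its manifest TSV, deterministically.

    Entries are ordered by (component, entry_id). The manifest counts are
    re-verified against the records written; a mismatch raises.
    """
    path = Path(path)
    manifest_path = (
        Path(manifest_path)
        if manifest_path is not None
        else path.with_suffix(".manifest.tsv")
    )
    ordered = sorted(entries, key=_component_order)
    written = collections.Counter(e.component for e in ordered)
    for comp in COMPONENTS:
        if written.get(comp, 0) != manifest.counts.get(comp, 0):
            raise ValueError(
                f"manifest/count mismatch for {comp}: manifest says "
                f"{manifest.counts.get(comp, 0)}, writing {written.get(comp, 0)}"
            )
    with open(path, "w") as fh:
        for e in ordered:
            fh.write(f">{_header(e)}\n{e.sequence}\n")

    rows = [{"key": f"count_{c}", "value": manifest.counts.get(c, 0)} for c in COMPONENTS]
    rows += [{"key": f"param_{k}", "value": v} for k, v in sorted(manifest.build_params.items())]
    rows += [{"key": f"sha256_{k}", "value": v} for k, v in sorted(manifest.input_digests.items())]
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def file_digest(path: str | Path) -> str:
    """sha256 hex digest of a file, for manifest input tracking."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_header(line: str) -> tuple[str, str, EntryMeta | None, str | None]:
    fields = line[1:].rstrip("\n").split("|")
    comp, entry_id = fields[0], fields[1]
    kv = dict(f.split("=", 1) for f in fields[2:])
    meta = None
    if "junction_aa" in kv:
        ga, gb = kv["genes"].split(":")
        ea, eb = kv["exons"].split(":")
        meta = EntryMeta(
            genes=(ga, gb),
            exons=(ea, eb),
            frame=int(kv["frame"]),
            junction_left_aa=int(kv["junction_aa"]),
            straddle=bool(int(kv.get("straddle", 0))),
            n_merged=int(kv.get("n_prov", 0)),
        )
    mirror = entry_id[len(DECOY_PREFIX):] if entry_id.startswith(DECOY_PREFIX) else None
    return comp, entry_id, meta, mirror


def read_database(path: str | Path) -> "PeptideDatabase":
    """Load a written database FASTA back into a :class:`PeptideDatabase`."""
    entries: list[DatabaseEntry] = []
    header: tuple[str, str, EntryMeta | None, str | None] | None = None
    seq_lines: list[str] = []

    def flush() -> None:
        if header is not None:
            comp, entry_id, meta, mirror = header
            entries.append(
                DatabaseEntry(
                    entry_id=entry_id,
                    component=comp,
                    sequence="".join(seq_lines),
                    meta=meta,
                    mirror_of=mirror,
                )
            )

    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                flush()
                header = _parse_header(line)
                seq_lines = []
            else:
                seq_lines.append(line.strip())
        flush()
    return PeptideDatabase(entries)


class PeptideDatabase:
    """Indexed view over assembled entries answering membership queries."""

    def __init__(self, entries: Iterable[DatabaseEntry]):
        self.entries = sorted(entries, key=_component_order)
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = [i for i, n in collections.Counter(ids).items() if n > 1]
            raise ValueError(f"duplicate entry ids: {dupes[:5]}")
        self._by_id = {e.entry_id: e for e in self.entries}
        self._by_component: dict[str, list[DatabaseEntry]] = {
            c: [] for c in COMPONENTS
        }
        for e in self.entries:
            self._by_component[e.component].append(e)
        # concatenated blobs ('|'-separated) give a fast negative substring test
        self._blob = {
            c: "|".join(e.sequence for e in self._by_component[c])
            for c in COMPONENTS
        }

    def __len__(self) -> int:
        return len(self.entries)

    def component(self, name: str) -> list[DatabaseEntry]:
        return self._by_component[name]

    def get(self, entry_id: str) -> DatabaseEntry:
        return self._by_id[entry_id]

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id

    def counts(self) -> dict[str, int]:
        return {c: len(self._by_component[c]) for c in COMPONENTS}

    def is_decoy_entry(self, entry_id: str) -> bool:
        e = self._by_id.get(entry_id)
        if e is not None:
            return e.component == "Reversal"
        return entry_id.startswith(DECOY_PREFIX)

    def is_decoy_peptide(self, seq: str) -> bool:
        """True when ``seq`` occurs in the Reversal component."""
        return seq in self._blob["Reversal"]

    def junction_matches(
        self, seq: str, component: str
    ) -> list[tuple[DatabaseEntry, int]]:
        """(entry, offset) pairs where ``seq`` occurs spanning the junction.

        A match counts only if it covers at least one pure-upstream and
        one pure-downstream residue of the entry's junction.
        """
        if component not in ("Fusion", "Splicing"):
            raise ValueError("junction_matches applies to Fusion/Splicing only")
        if seq not in self._blob[component]:
            return []
        hits = []
        for e in self._by_component[component]:
            start = e.sequence.find(seq)
            while start != -1:
                if _spans_junction(e, start, len(seq)):
                    hits.append((e, start))
                start = e.sequence.find(seq, start + 1)
        return hits

    def membership(self, seq: str) -> set[str]:
        """Components a peptide belongs to, under the substring semantics.

        Annotated/Contaminated membership means substring of any protein;
        Fusion/Splicing membership additionally requires the match to span
        the entry's junction with >=1 pure residue on each side.
        """
        if not seq:
            raise ValueError("empty query peptide")
        out = set()
        for comp in ("Annotated", "Contaminated"):
            # '|' never occurs in a peptide, so a blob hit is an exact
            # single-protein substring hit
            if seq in self._blob[comp]:
                out.add(comp)
        for comp in ("Fusion", "Splicing"):
            if self.junction_matches(seq, comp):
                out.add(comp)
        return out


def _spans_junction(entry: DatabaseEntry, offset: int, length: int) -> bool:
    if entry.meta is None:
        raise ValueError(f"entry {entry.entry_id} has no junction metadata")
    left = entry.meta.junction_left_aa
    down0 = left + (1 if entry.meta.straddle else 0)
    n_up = max(0, min(offset + length, left) - offset)
    n_down = max(0, offset + length - max(offset, down0))
    return n_up >= 1 and n_down >= 1
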