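"""Control panels of recurrently observed splicing junctions.

A panel is the set of junctions seen often enough across a reference cohort
that their reappearance in a new sample is not considered aberrant.  Two
construction rules are supported: the plain cohort rule (>= min_reads reads
in >= min_samples distinct samples) and the tissue-aware rule used for
multi-tissue cohorts, where the individual threshold must be reached within
a single tissue.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from sscv.models import SpliceJunction

PathLike = Union[str, Path]

JunctionKey = tuple[str, int, int]


class ControlPanel:
    """Exact-key membership set of junction (chrom, intron_start, intron_end)."""

    def __init__(self, keys: Iterable[JunctionKey] = (), provenance: dict | None = None):
        self.keys: set[JunctionKey] = {(c, int(s), int(e)) for c, s, e in keys}
        self.provenance: dict = dict(provenance or {})

    def __contains__(self, junction) -> bool:
        return self.contains(junction)

    def __len__(self) -> int:
        return len(self.keys)

    def contains(self, junction) -> bool:
        if isinstance(junction, SpliceJunction):
            return junction.key in self.keys
        chrom, start, end = junction
        return (chrom, int(start), int(end)) in self.keys

    def save(self, path: PathLike) -> None:
        """Serialize as sorted gzip TSV with thresholds in the header."""
        meta = ";".join(f"{k}={v}" for k, v in sorted(self.provenance.items()))
        with gzip.open(str(path), "wt") as fh:
            fh.write(f"#panel {meta}\n")
            fh.write("chrom\tintron_start\tintron_end\n")
            for chrom, start, end in sorted(self.keys):
                fh.write(f"{chrom}\t{start}\t{end}\n")

    @classmethod
    def load(cls, path: PathLike) -> "ControlPanel":
        keys = []
        provenance = {}
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "rt") as fh:
            for line in fh:
                if line.startswith("#panel"):
                    for item in line.split(None, 1)[1].strip().split(";"):
                        if "=" in item:
                            k, v = item.split("=", 1)
                            provenance[k] = v
                    continue
                if line.startswith("chrom") or not line.strip():
                    continue
                chrom, start, end = line.rstrip("\n").split("\t")
                keys.append((chrom, int(start), int(end)))
        return cls(keys, provenance)


def _per_sample_keys(junctions: Sequence[SpliceJunction], min_reads: int) -> set[JunctionKey]:
    # duplicate rows within one sample count once; reads are not summed
    return {j.key for j in junctions if j.unique_reads >= min_reads}


def build_panel(
    junction_files: Sequence[Sequence[SpliceJunction]],
    min_reads: int = 2,
    min_samples: int = 4,
) -> ControlPanel:
    """Junctions supported by >= min_reads reads in >= min_samples samples."""
    if not junction_files:
        raise ValueError("at least one sample junction list is required")
    counts: dict[JunctionKey, int] = defaultdict(int)
    for sample in junction_files:
        for key in _per_sample_keys(sample, min_reads):
            counts[key] += 1
    keys = {key for key, n in counts.items() if n >= min_samples}
    return ControlPanel(
        keys,
        {"rule": "cohort", "n_samples": len(junction_files),
         "min_reads": min_reads, "min_samples": min_samples},
    )


def build_tissue_panel(
    files: Mapping[tuple[str, str], Sequence[SpliceJunction]],
    min_reads: int = 2,
    min_individuals: int = 8,
) -> ControlPanel:
    """Tissue-aware panel rule.

    ``files`` maps (individual, tissue) to that sample's junction list.  A
    junction enters the panel when, within ANY single tissue, at least
    ``min_individuals`` distinct individuals show >= ``min_reads`` reads.
    """
    per_tissue: dict[str, dict[JunctionKey, set[str]]] = defaultdict(lambda: defaultdict(set))
    individuals = set()
    for (individual, tissue), junctions in files.items():
        individuals.add(individual)
        for key in _per_sample_keys(junctions, min_reads):
            per_tissue[tissue][key].add(individual)
    keys = {
        key
        for tissue_map in per_tissue.values()
        for key, carriers in tissue_map.items()
        if len(carriers) >= min_individuals
    }
    return ControlPanel(
        keys,
        {"rule": "per_tissue", "n_individuals": len(individuals),
         "min_reads": min_reads, "min_individuals": min_individuals},
    )


def panel_contains(panel: ControlPanel, junction) -> bool:
    return panel.contains(junction)
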