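"""Contaminant filtering: partition unique tags into mRNA, Rfam classes
(rRNA/tRNA/snRNA/snoRNA/other ncRNA) and repeats versus valid tags, and
format the per-library accounting table.

Matching is substring containment (up to a configurable number of
substitutions, default 1) against the category references on either
strand.  When a tag hits several databases the first category in priority
order repeat > rRNA > tRNA > snoRNA > snRNA > other_ncRNA > mRNA wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

from ._seq import SubstringIndex

CONTAMINANT_CATEGORIES = (
    "mRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA", "repeat")

RFAM_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA", "other_ncRNA")

# First hit in this order wins when a tag matches several databases.
DEFAULT_PRIORITY = (
    "repeat", "rRNA", "tRNA", "snoRNA", "snRNA", "other_ncRNA", "mRNA")


@dataclass
class RefRecord:
    id: str
    seq: str
    species: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty reference sequence for {self.id}")


@dataclass
class ReferenceBundle:
    """Categorised reference sequence sets driving filtering/classification."""

    genome: dict[str, str] = field(default_factory=dict)
    mature: list[RefRecord] = field(default_factory=list)
    premirna: list[RefRecord] = field(default_factory=list)
    mature_to_pre: dict[str, str] = field(default_factory=dict)
    categories: dict[str, list[RefRecord]] = field(default_factory=dict)
    focal_species: str = "chi"
    species: list[str] = field(default_factory=list)
    _indices: dict[str, SubstringIndex] = field(default_factory=dict, repr=False)

    def index(self, category: str) -> SubstringIndex:
        if category not in self._indices:
            recs = self.categories.get(category, [])
            self._indices[category] = SubstringIndex([r.seq for r in recs])
        return self._indices[category]

    # -- directory round trip (FASTA per category + YAML manifest) ----------
    def save(self, outdir) -> None:
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "focal_species": self.focal_species,
            "species": self.species,
            "mature_to_pre": self.mature_to_pre,
            "files": {},
        }

        def dump(name, recs, with_species=False):
            path = outdir / f"{name}.fa"
            with open(path, "w") as fh:
                for r in recs:
                    sp = f" species={r.species}" if with_species and r.species else ""
                    fh.write(f">{r.id}{sp}\n{r.seq}\n")
            manifest["files"][name] = path.name

        dump("mature_mirna", self.mature, with_species=True)
        dump("pre_mirna", self.premirna, with_species=True)
        for cat, recs in self.categories.items():
            dump(cat, recs)
        with open(outdir / "genome.fa", "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n{seq}\n")
        manifest["files"]["genome"] = "genome.fa"
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)

    @classmethod
    def load(cls, indir) -> "ReferenceBundle":
        import yaml

        from Bio import SeqIO

        indir = Path(indir)
        with open(indir / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)

        def parse(path, with_species=False):
            recs = []
            for rec in SeqIO.parse(indir / path, "fasta"):
                species = None
                if with_species:
                    for token in rec.description.split():
                        if token.startswith("species="):
                            species = token.split("=", 1)[1]
                recs.append(RefRecord(rec.id, str(rec.seq), species))
            return recs

        files = manifest["files"]
        genome = {rec.id: str(rec.seq)
                  for rec in SeqIO.parse(indir / files["genome"], "fasta")}
        categories = {
            cat: parse(files[cat])
            for cat in CONTAMINANT_CATEGORIES if cat in files
        }
        return cls(
            genome=genome,
            mature=parse(files["mature_mirna"], with_species=True),
            premirna=parse(files["pre_mirna"], with_species=True),
            mature_to_pre=manifest.get("mature_to_pre", {}),
            categories=categories,
            focal_species=manifest["focal_species"],
            species=manifest["species"],
        )


def match_category(
    tag: str,
    bundle: ReferenceBundle,
    max_mismatch: int = 1,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> Optional[str]:
    """First category (in priority order) containing the tag, or None."""
    for cat in priority:
        idx = bundle.index(cat)
        if idx and idx.contains(tag, max_mismatch=max_mismatch):
            return cat
    return None


def percent_of(count: int, total: int) -> float:
    """Percentage of ``total``, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive to compute percentages")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def library_stats(category_counts: dict[str, int], raw_total: int) -> "object":
    """Accounting table: per category, count and percentage of raw total.

    ``category_counts`` may contain any mix of dispositions and contaminant
    categories; an ``Rfam`` supercategory row (sum of the five Rfam
    classes) is added when any of them is present.
    """
    import pandas as pd

    counts = dict(category_counts)
    if any(c in counts for c in RFAM_CLASSES):
        counts = {"Rfam": sum(counts.get(c, 0) for c in RFAM_CLASSES), **counts}
    rows = [
        {"category": cat, "count": n, "percent": percent_of(n, raw_total)}
        for cat, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def partition_valid(
    tag_df,
    bundle: ReferenceBundle,
    raw_totals: dict[str, int],
    max_mismatch: int = 1,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
):
    """Split a tag table into valid tags and per-category accounting.

    Every tag is assigned exactly one contaminant category or stays valid.
    Returns ``(valid_tag_df, stats)`` where ``stats`` is a DataFrame with
    one row per (library, category) carrying total-read and unique-tag
    counts plus percentages of the library's raw total.
    """
    import pandas as pd

    if not raw_totals:
        raise ValueError("raw totals are required to compute percentages")

    assignment = {
        tag: match_category(tag, bundle, max_mismatch, priority) or "valid"
        for tag in tag_df.index
    }
    cat_series = pd.Series(assignment, name="category")
    libs = [c.removeprefix("count_") for c in tag_df.columns if c.startswith("count_")]
    rows = []
    for lib in libs:
        counts = tag_df[f"count_{lib}"]
        present = counts > 0
        grouped = counts.groupby(cat_series).sum()
        uniq = present.groupby(cat_series).sum()
        all_cats = list(DEFAULT_PRIORITY) + ["valid"]
        tallies = {c: int(grouped.get(c, 0)) for c in all_cats}
        tallies["Rfam"] = sum(tallies[c] for c in RFAM_CLASSES)
        for cat in ["repeat", "Rfam", *RFAM_CLASSES, "mRNA", "valid"]:
            n = tallies[cat]
            u = (sum(int(uniq.get(c, 0)) for c in RFAM_CLASSES)
                 if cat == "Rfam" else int(uniq.get(cat, 0)))
            rows.append({
                "library": lib, "category": cat,
                "reads": n, "percent": percent_of(n, raw_totals[lib]),
                "unique": u,
            })
    stats = pd.DataFrame(rows)
    valid = tag_df.loc[[t for t, c in assignment.items() if c == "valid"]]
    return valid, stats
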