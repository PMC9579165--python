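"""Domain types for the knockout-proteomics screen.

The screen quantifies proteins across thousands of single-gene knockout
strains using TMT 10plex multiplexing: each mass-spectrometry run carries
eight knockout samples, one technical spike-in control (a single frozen
wild-type lysate, always on the 127C channel) and one biological wild-type
control grown alongside the knockouts (130N channel).  The types here are
thin, validated wrappers around pandas objects so every downstream stage
can rely on a consistent vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class FormatError(ValueError):
    """Raised when a file does not have the expected layout."""


#: TMT 10plex reporter channel names, in mass order.
TMT10_CHANNELS = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)

#: Channel reserved for the technical spike-in wild-type reference.
TECHNICAL_CHANNEL = "127C"
#: Channel reserved for the per-run biological wild-type control.
BIOLOGICAL_CHANNEL = "130N"

SAMPLE_TYPES = ("knockout", "wt_biological", "wt_technical")

#: The 64 codons in fixed (alphabetical) order; every codon-indexed table
#: in the package uses this ordering.
ALL_CODONS = tuple("".join(c) for c in _iterproduct("ACGT", repeat=3))

MANIFEST_COLUMNS = (
    "sample_id", "strain_id", "sample_type", "plate_id", "well", "run_id", "channel",
)


@dataclass
class SampleManifest:
    """Sample ↔ run ↔ plate ↔ channel map for a multiplexed screen.

    Wraps a DataFrame with columns ``sample_id, strain_id, sample_type,
    plate_id, well, run_id, channel``.  Channels must be TMT10 label names
    and unique within a run; sample ids are globally unique.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        df = df.loc[:, list(MANIFEST_COLUMNS)].reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        bad_type = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValidationError(f"unknown sample types: {sorted(bad_type)}")
        bad_chan = set(df["channel"]) - set(TMT10_CHANNELS)
        if bad_chan:
            raise ValidationError(f"unknown TMT channels: {sorted(bad_chan)}")
        per_run = df.groupby("run_id")["channel"]
        if (per_run.nunique() != per_run.size()).any():
            raise ValidationError("channel reused within a run")
        if (per_run.size() > 10).any():
            big = per_run.size()[per_run.size() > 10].index.tolist()
            raise ValidationError(f"runs with more than 10 channels: {big}")
        object.__setattr__(self, "frame", df)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def run_ids(self) -> list[str]:
        return self.frame["run_id"].drop_duplicates().tolist()

    def samples_of_type(self, sample_type: str) -> list[str]:
        df = self.frame
        return df.loc[df["sample_type"] == sample_type, "sample_id"].tolist()

    def run_of(self) -> pd.Series:
        """sample_id → run_id."""
        return self.frame.set_index("sample_id")["run_id"]

    def plate_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["plate_id"]

    def strain_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["strain_id"]

    def technical_samples(self) -> pd.Series:
        """run_id → sample_id of its technical spike-in; raises if absent."""
        df = self.frame
        tech = df[df["sample_type"] == "wt_technical"]
        missing = sorted(set(df["run_id"]) - set(tech["run_id"]))
        if missing:
            raise ValidationError(
                f"runs without a technical (127C) control: {missing}"
            )
        return tech.set_index("run_id")["sample_id"]


@dataclass
class RunLayout:
    """Per-run design report from :func:`validate_layout`."""

    per_run: pd.DataFrame  # index run_id; n_knockout, n_wt_biological, n_wt_technical, n_channels, conforms
    n_samples: int         # knockout + biological samples (technical excluded)
    n_runs: int

    @property
    def nonconforming_runs(self) -> list[str]:
        return self.per_run.index[~self.per_run["conforms"]].tolist()


def validate_layout(manifest: SampleManifest) -> RunLayout:
    """Check the 8-knockout + technical(127C) + biological(130N) run design.

    A run lacking a technical or biological control is an error; a run with
    a knockout count other than 8 is merely flagged (partial runs occur at
    the end of a plate).  Pure: the same manifest yields the same report.
    """
    df = manifest.frame
    counts = (
        df.pivot_table(index="run_id", columns="sample_type",
                       values="sample_id", aggfunc="count")
        .reindex(columns=SAMPLE_TYPES)
        .fillna(0)
        .astype(int)
    )
    counts.columns = [f"n_{c}" for c in counts.columns]
    for kind, chan in (("wt_technical", TECHNICAL_CHANNEL),
                       ("wt_biological", BIOLOGICAL_CHANNEL)):
        bad = counts.index[counts[f"n_{kind}"] != 1].tolist()
        if bad:
            raise ValidationError(
                f"runs without exactly one {kind} ({chan}) control: {bad}"
            )
        sub = df[df["sample_type"] == kind]
        off = sub.loc[sub["channel"] != chan, "run_id"].tolist()
        if off:
            raise ValidationError(
                f"{kind} control not on channel {chan} in runs: {off}"
            )
    counts["n_channels"] = df.groupby("run_id")["channel"].nunique().reindex(counts.index)
    counts["conforms"] = (
        (counts["n_knockout"] == 8)
        & (counts["n_wt_technical"] == 1)
        & (counts["n_wt_biological"] == 1)
    )
    n_samples = int((df["sample_type"] != "wt_technical").sum())
    return RunLayout(per_run=counts, n_samples=n_samples, n_runs=len(counts))


@dataclass
class IntensityMatrix:
    """Proteins × samples quantification matrix.

    ``scale`` is one of ``raw`` (reporter intensities, strictly positive),
    ``log`` (log2) or ``normalized`` (log2 after cross-run normalization).
    Missing values are NaN; a raw intensity of zero is a non-quantification
    and is stored as missing.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log", "normalized"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate protein ids")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        data = self.data.astype(float)
        if self.scale == "raw":
            vals = data.to_numpy()
            data = data.mask(pd.DataFrame(vals == 0.0, index=data.index,
                                          columns=data.columns))
            vals = data.to_numpy()
            if vals.size and not np.all(np.isnan(vals)) and np.nanmin(vals) < 0:
                raise ValidationError("raw intensities must be positive")
        object.__setattr__(self, "data", data)

    @property
    def protein_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def to_log2(self) -> "IntensityMatrix":
        if self.scale != "raw":
            return self
        with np.errstate(divide="ignore", invalid="ignore"):
            return IntensityMatrix(np.log2(self.data), scale="log")


@dataclass
class TranscriptMatrix:
    """Genes × samples log2 CPM matrix; entries below the global CPM filter
    quantile are removed (stored missing) before construction."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        object.__setattr__(self, "data", self.data.astype(float))

    @staticmethod
    def from_cpm(cpm: pd.DataFrame, filter_quantile: float = 0.25) -> "TranscriptMatrix":
        """Apply the global low-expression filter and log2-transform.

        CPM values below the ``filter_quantile`` of all observed CPM values
        are marked missing, then values are log2-transformed.
        """
        vals = cpm.to_numpy(dtype=float)
        cutoff = np.nanquantile(vals, filter_quantile)
        filtered = cpm.mask(cpm < cutoff)
        with np.errstate(divide="ignore", invalid="ignore"):
            return TranscriptMatrix(np.log2(filtered))


@dataclass
class AnnotationNetwork:
    """Undirected protein-association network with 0–1000 combined scores.

    Edges are stored once, in canonical (sorted) order, self-edges dropped.
    """

    edges: pd.DataFrame  # protein_a, protein_b, combined_score

    def __post_init__(self) -> None:
        df = self.edges
        need = ["protein_a", "protein_b", "combined_score"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise FormatError(f"edge list missing columns: {missing}")
        df = df.loc[:, need].copy()
        score = df["combined_score"].astype(int)
        if ((score < 0) | (score > 1000)).any():
            raise ValidationError("combined scores must lie in [0, 1000]")
        df["combined_score"] = score
        a = df["protein_a"].astype(str)
        b = df["protein_b"].astype(str)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        df["protein_a"], df["protein_b"] = lo, hi
        df = df[df["protein_a"] != df["protein_b"]]
        # keep the maximal score for duplicated pairs
        df = (
            df.sort_values("combined_score")
            .drop_duplicates(["protein_a", "protein_b"], keep="last")
            .sort_values(["protein_a", "protein_b"])
            .reset_index(drop=True)
        )
        object.__setattr__(self, "edges", df)

    def associated_pairs(self, score_threshold: int = 150) -> set[tuple[str, str]]:
        """Pairs with combined score strictly greater than the threshold."""
        df = self.edges
        keep = df[df["combined_score"] > score_threshold]
        return set(zip(keep["protein_a"], keep["protein_b"]))

    @property
    def node_ids(self) -> list[str]:
        return sorted(set(self.edges["protein_a"]) | set(self.edges["protein_b"]))


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-style annotation carrier)."""

    sets: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if len(v) == 0]
        if empty:
            raise ValidationError(f"empty gene sets: {empty}")
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, key: str) -> frozenset[str]:
        return self.sets[key]

    def items(self):
        return self.sets.items()


_DNA = frozenset("ACGT")


@dataclass
class ORFSet:
    """gene id → coding DNA sequence, frame-valid and ACGT-only."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for gene, seq in self.sequences.items():
            seq = str(seq).upper()
            if len(seq) % 3 != 0:
                raise ValidationError(
                    f"ORF {gene}: length {len(seq)} not divisible by 3"
                )
            if not set(seq) <= _DNA:
                raise ValidationError(
                    f"ORF {gene}: non-ACGT symbols {sorted(set(seq) - _DNA)}"
                )
            clean[gene] = seq
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene: str) -> str:
        return self.sequences[gene]

    def items(self):
        return self.sequences.items()


@dataclass
class CodonTable:
    """Optimality flag for each of the 64 codons.

    Optimal codons are the synonymous codons decoded by high-abundance
    tRNAs; the flag assignment is an input (measured sets differ between
    organisms).
    """

    optimal: pd.Series  # bool, indexed by the 64 codons

    def __post_init__(self) -> None:
        s = self.optimal
        if len(s) != 64:
            raise ValidationError(f"codon table must have 64 entries, got {len(s)}")
        if set(s.index) != set(ALL_CODONS):
            raise ValidationError("codon table index must be the 64 codons")
        object.__setattr__(
            self, "optimal", s.reindex(list(ALL_CODONS)).astype(bool)
        )

    @property
    def optimal_codons(self) -> list[str]:
        return self.optimal.index[self.optimal].tolist()


def default_codon_table() -> CodonTable:
    """A synthetic codon-optimality assignment for simulations.

    Marks one codon per synonymous family with at least two members
    (lexicographically first) as optimal; stop codons and single-codon
    families (Met, Trp) are non-optimal.  This is a synthetic stand-in with
    the same combinatorial shape as an empirically measured optimality set,
    used by the data generator and examples; real analyses should load a
    measured table via :func:`proteoscan.io.read_codon_table`.
    """
    from Bio.Data.CodonTable import standard_dna_table

    fwd = standard_dna_table.forward_table  # codon -> amino acid
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        codon_u = codon.replace("T", "T")
        aa = fwd.get(codon_u)
        if aa is None:
            continue  # stop codon
        families.setdefault(aa, []).append(codon)
    flags = pd.Series(False, index=list(ALL_CODONS))
    for aa, codons in families.items():
        if len(codons) >= 2:
            flags[min(codons)] = True
    return CodonTable(flags)


@dataclass
class GrowthTable:
    """Per-strain growth measurements (OD600) with the plate they grew on."""

    frame: pd.DataFrame  # strain_id, plate_id, od600 [, growth_z]

    def __post_init__(self) -> None:
        need = ["strain_id", "plate_id", "od600"]
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise FormatError(f"growth table missing columns: {missing}")
        if self.frame["strain_id"].duplicated().any():
            raise ValidationError("duplicate strain ids in growth table")


def make_manifest(records: Iterable[Mapping]) -> SampleManifest:
    """Build a manifest from an iterable of record dicts."""
    return SampleManifest(pd.DataFrame(list(records)))
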