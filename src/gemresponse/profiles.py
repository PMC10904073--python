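"""Per-profile preprocessing of tumor molecular matrices.

Eight profile kinds are supported: mRNA expression in FPKM and
upper-quartile FPKM, miRNA and isomiR log2-RPM, CpG-probe methylation beta
values, per-island mean beta (CGI), and per-gene mean/median copy number
aggregated from DNA segments. Preprocessing is deliberately minimal — the
matrices arrive normalized, as from a standard pipeline — and consists of
removing features with any missing value, the log2 transform for
read-count-per-million data, probe-to-island averaging, segment-to-gene
aggregation, and profile concatenation for the data-integration runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROFILE_KINDS = (
    "fpkm",
    "fpkm_uq",
    "mirna_log2rpm",
    "isomir_log2rpm",
    "cpg_beta",
    "cgi_beta",
    "cnv_mean",
    "cnv_median",
    "clinical",
)

_BETA_KINDS = ("cpg_beta", "cgi_beta")
_NONNEG_KINDS = ("fpkm", "fpkm_uq")


@dataclass
class OmicsProfile:
    """A sample x feature numeric matrix tagged with its profile kind.

    The kind governs value-range invariants: beta-value kinds must lie in
    [0, 1], FPKM kinds must be non-negative. Composite kinds (from
    concatenation) carry a ``+``-joined tag and skip range checks.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated feature ids: {dupes[:5]}")
        finite = self.values.to_numpy(dtype=float)
        if self.kind in _BETA_KINDS:
            observed = finite[~np.isnan(finite)]
            if observed.size and (observed.min() < 0 or observed.max() > 1):
                raise ValueError(f"{self.kind} values must lie in [0, 1]")
        if self.kind in _NONNEG_KINDS:
            observed = finite[~np.isnan(finite)]
            if observed.size and observed.min() < 0:
                raise ValueError(f"{self.kind} values must be non-negative")

    @property
    def sample_ids(self) -> List[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_ids(self) -> List[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def read_profile_tsv(path, kind: str) -> OmicsProfile:
    """Read a features x samples TSV (the on-disk layout) into a profile."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsProfile(frame.T, kind=kind)


def drop_incomplete_features(profile: OmicsProfile) -> OmicsProfile:
    """Remove every feature with at least one missing value across samples.

    The sample set is unchanged. Raises if nothing survives.
    """
    complete = profile.values.columns[profile.values.notna().all(axis=0)]
    removed = profile.n_features - len(complete)
    if len(complete) == 0:
        raise ValueError("all features contain missing values")
    if removed:
        logger.info("dropped %d incomplete features (%d remain)", removed, len(complete))
    return OmicsProfile(profile.values[complete].copy(), kind=profile.kind)


def log2_rpm(profile: OmicsProfile, pseudocount: float = 1.0) -> OmicsProfile:
    """log2(x + pseudocount) transform for RPM-scale read counts.

    The default pseudocount of 1 keeps zero counts finite (log2(0+1) = 0).
    """
    arr = profile.values.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("log2-RPM transform requires non-negative values")
    transformed = np.log2(arr + pseudocount)
    kind = "mirna_log2rpm" if "isomir" not in profile.kind else "isomir_log2rpm"
    return OmicsProfile(
        pd.DataFrame(transformed, index=profile.values.index, columns=profile.values.columns),
        kind=kind,
    )


def aggregate_probes_to_islands(
    profile: OmicsProfile, probe_island_map: Dict[str, str]
) -> OmicsProfile:
    """CGI profile: per-island arithmetic mean of mapped probe beta values.

    Each mapped probe belongs to exactly one island; probes absent from the
    map (shore/shelf or unannotated probes) are dropped. Means of values in
    [0, 1] stay in [0, 1].
    """
    if profile.kind != "cpg_beta":
        raise ValueError(f"expected a cpg_beta profile, got {profile.kind}")
    if not probe_island_map:
        raise ValueError("empty probe-to-island map")
    mapped = [p for p in profile.feature_ids if p in probe_island_map]
    if not mapped:
        raise ValueError("no profile probe appears in the map")
    islands = pd.Series({p: probe_island_map[p] for p in mapped})
    grouped = profile.values[mapped].T.groupby(islands).mean().T
    grouped = grouped[sorted(grouped.columns)]
    return OmicsProfile(grouped, kind="cgi_beta")


def aggregate_segments_to_genes(
    segments: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    stat: str = "mean",
) -> OmicsProfile:
    """Per-gene copy number from overlapping DNA segments.

    For each sample and gene, collect the values of all segments whose
    interval overlaps the gene interval by at least 1 bp (0-based half-open
    coordinates: overlap iff ``seg.start < gene.end and seg.end >
    gene.start``) and reduce with *stat* (``mean`` or ``median``). Genes
    with no overlapping segment in a sample get a missing value, to be
    removed later by :func:`drop_incomplete_features`.

    ``segments`` columns: sample_id, chrom, start, end, value;
    ``gene_intervals`` columns: gene_id, chrom, start, end.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    for frame, name in ((segments, "segments"), (gene_intervals, "gene_intervals")):
        if (frame["start"] >= frame["end"]).any():
            raise ValueError(f"malformed intervals in {name}: start >= end")
    reduce = np.mean if stat == "mean" else np.median
    sample_order = list(dict.fromkeys(segments["sample_id"]))
    gene_ids = gene_intervals["gene_id"].tolist()
    out = np.full((len(sample_order), len(gene_ids)), np.nan)
    for si, (sid, seg) in enumerate(segments.groupby("sample_id", sort=False)):
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        chroms = seg["chrom"].to_numpy()
        vals = seg["value"].to_numpy(dtype=float)
        for gi, g in enumerate(gene_intervals.itertuples(index=False)):
            hit = (chroms == g.chrom) & (starts < g.end) & (ends > g.start)
            if hit.any():
                out[si, gi] = reduce(vals[hit])
    frame = pd.DataFrame(out, index=sample_order, columns=gene_ids)
    return OmicsProfile(frame, kind=f"cnv_{stat}")


def concatenate_profiles(profiles: Sequence[OmicsProfile]) -> OmicsProfile:
    """Join profiles on their common samples, namespacing feature IDs.

    Feature IDs become ``<kind>:<feature_id>`` so identical IDs from
    different assays cannot collide; the result's kind is the ``+``-joined
    composite tag. Samples are the inner intersection, in the first
    profile's order.
    """
    if not profiles:
        raise ValueError("no profiles to concatenate")
    common = profiles[0].values.index
    for p in profiles[1:]:
        common = common.intersection(p.values.index)
    if len(common) == 0:
        raise ValueError("profiles share no samples")
    common = [s for s in profiles[0].sample_ids if s in set(common)]
    blocks = []
    for p in profiles:
        block = p.values.loc[common].copy()
        block.columns = [f"{p.kind}:{c}" for c in block.columns]
        blocks.append(block)
    joined = pd.concat(blocks, axis=1)
    return OmicsProfile(joined, kind="+".join(p.kind for p in profiles))


def encode_clinical(table: pd.DataFrame) -> OmicsProfile:
    """Numeric clinical-feature matrix: one-hot categoricals, passthrough numerics.

    The input is indexed by sample/patient ID. Categorical (object) columns
    are expanded with ``<column>=<level>`` feature names; numeric columns
    pass through unchanged.
    """
    numeric = table.select_dtypes(include=[np.number])
    categorical = table.select_dtypes(exclude=[np.number])
    blocks = [numeric]
    if not categorical.empty:
        onehot = pd.get_dummies(categorical, prefix_sep="=").astype(float)
        blocks.append(onehot)
    values = pd.concat(blocks, axis=1)
    return OmicsProfile(values, kind="clinical")
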