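"""Synthetic genomes, truth abundance profiles, counts and alignments.

The generator emulates the statistical structure of a far-red-light
acclimation experiment in a cyanobacterium: a ~20-gene photoacclimation
cluster that is nearly silent under white light and induced by three to
four orders of magnitude under far-red light; abolition of that induction
when the regulator genes rfpB/rfpC are deleted and weak residual induction
without rfpA; repression of phycobiliprotein/photosystem-I genes in
far-red light; and an independently inducible erythromycin-response gene
set. rRNA-derived reads and non-uniquely mapping reads are mixed in so the
pre-counting filters are exercised.

Truth abundances are compositions: induction factors multiply baseline
abundances and the vector is renormalized to sum to one, so the expected
(observable) ratio of a gene differs from its raw factor. The truth table
stores the post-renormalization abundances and all expected ratios are
derived from them.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .alignments import AlignmentRecord, FilterStats
from .annotation import GenomeAnnotation, GenomicFeature
from .counting import CountTable


class CapacityError(ValueError):
    """The requested features do not fit on the reference."""


@dataclass
class RegulonSpec:
    """A gene set sharing condition-dependent expression factors.

    ``fold_factor_by_condition`` maps a condition to either one factor for
    the whole regulon or a per-member sequence (matching ``member_features``
    order). ``baseline_scale`` multiplies the drawn baseline abundance of
    every member, modelling genes that are nearly silent under the
    reference condition (without it, a strongly induced regulon would
    swallow the mRNA pool and the observable ratios would collapse).
    ``baseline_weight``, when set, replaces the drawn weight of every
    member with a fixed value (on the scale where the background law has
    median 1), pinning the members' baseline coverage.
    """

    name: str
    member_features: list[str]
    fold_factor_by_condition: dict[str, float | list[float]]
    baseline_scale: float = 1.0
    baseline_weight: float | None = None

    def __post_init__(self) -> None:
        for cond, fac in self.fold_factor_by_condition.items():
            vals = np.atleast_1d(np.asarray(fac, dtype=float))
            if np.any(vals <= 0):
                raise ValueError(
                    f"regulon {self.name!r}: factors for {cond!r} must be > 0"
                )
            if vals.size not in (1, len(self.member_features)):
                raise ValueError(
                    f"regulon {self.name!r}: factor list for {cond!r} must have "
                    f"1 or {len(self.member_features)} entries"
                )
        if self.baseline_scale <= 0:
            raise ValueError(f"regulon {self.name!r}: baseline_scale must be > 0")
        if self.baseline_weight is not None and self.baseline_weight <= 0:
            raise ValueError(f"regulon {self.name!r}: baseline_weight must be > 0")

    def factors(self, condition_id: str) -> np.ndarray:
        fac = self.fold_factor_by_condition.get(condition_id, 1.0)
        vals = np.atleast_1d(np.asarray(fac, dtype=float))
        if vals.size == 1:
            vals = np.repeat(vals, len(self.member_features))
        return vals


@dataclass
class SimulationConfig:
    """Everything needed to regenerate a study scenario from a seed."""

    n_orfs: int = 200
    orf_length_range: tuple[int, int] = (300, 3000)
    reference_length: int = 600_000
    reference_name: str = "genome"
    regulons: list[RegulonSpec] = field(default_factory=list)
    baseline_abundance_law: str = "lognormal:1.0"  # or "uniform"
    conditions: dict[str, int] = field(default_factory=lambda: {"baseline": 1})
    depth: int = 100_000
    rrna_fraction: float = 0.0
    non_unique_fraction: float = 0.0
    read_length: int = 100
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rrna_fraction < 1 or not 0 <= self.non_unique_fraction < 1:
            raise ValueError("contamination fractions must be in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        members: set[str] = set()
        for reg in self.regulons:
            overlap = members & set(reg.member_features)
            if overlap:
                raise ValueError(f"regulon memberships overlap: {sorted(overlap)[:5]}")
            members |= set(reg.member_features)

    def to_json(self, path: str) -> None:
        doc = asdict(self)
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        doc = dict(doc)
        doc["regulons"] = [RegulonSpec(**r) for r in doc.get("regulons", [])]
        if "orf_length_range" in doc:
            doc["orf_length_range"] = tuple(doc["orf_length_range"])
        return cls(**doc)


class TruthTable:
    """Post-renormalization truth abundances per condition.

    ``abundance(cond)`` returns the per-ORF composition (sums to 1);
    ``expected_ratio(baseline, other)`` returns the observable per-gene
    ratios implied by the renormalized compositions.
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        abundances: Mapping[str, np.ndarray],
        regulon_members: Mapping[str, list[str]],
    ) -> None:
        self.feature_ids = list(feature_ids)
        self._abund = {c: np.asarray(a, dtype=float) for c, a in abundances.items()}
        self.regulon_members = {k: list(v) for k, v in regulon_members.items()}
        for cond, vec in self._abund.items():
            if abs(vec.sum() - 1.0) > 1e-12:
                raise ValueError(f"truth for {cond!r} does not sum to 1")

    @property
    def conditions(self) -> list[str]:
        return list(self._abund)

    def abundance(self, condition_id: str) -> dict[str, float]:
        if condition_id not in self._abund:
            raise KeyError(f"unknown condition {condition_id!r}")
        return dict(zip(self.feature_ids, self._abund[condition_id]))

    def abundance_vector(self, condition_id: str) -> np.ndarray:
        if condition_id not in self._abund:
            raise KeyError(f"unknown condition {condition_id!r}")
        return self._abund[condition_id]

    def expected_ratio(self, baseline: str, other: str) -> dict[str, float]:
        p1 = self.abundance_vector(baseline)
        p2 = self.abundance_vector(other)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p1 > 0, p2 / p1, np.nan)
        return dict(zip(self.feature_ids, ratio))

    def write_tsv(self, path: str) -> None:
        conds = self.conditions
        with open(path, "wt", encoding="utf-8") as fh:
            member_of = {
                fid: name
                for name, fids in self.regulon_members.items()
                for fid in fids
            }
            fh.write("feature_id\tregulon\t" + "\t".join(conds) + "\n")
            for i, fid in enumerate(self.feature_ids):
                vals = "\t".join(f"{self._abund[c][i]:.10g}" for c in conds)
                fh.write(f"{fid}\t{member_of.get(fid, '.')}\t{vals}\n")


def _rng_for(seed: int, condition_id: str, replicate: int, purpose: str = "counts"):
    """One independent stream per (seed, condition, replicate, purpose), so
    adding a condition or sample never perturbs the others."""
    key = (
        zlib.crc32(condition_id.encode()),
        replicate,
        zlib.crc32(purpose.encode()),
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def build_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthTable]:
    """Lay out non-overlapping ORFs plus one rRNA and one tRNA feature and
    derive the per-condition truth compositions.

    ORF identifiers are ``orf0001`` ... in genomic order; regulon members
    must name generated ORFs. Baseline abundances follow the configured
    law (uniform, or log-normal with the given sigma on the natural-log
    scale); condition abundances are baseline x factor, renormalized.
    """
    rng = _rng_for(config.seed, "__genome__", 0, "layout")
    lo, hi = config.orf_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_orfs)
    extra = [("rRNA", 2900), ("tRNA", 80)]
    # random insertion points for the structural RNA features
    order: list[tuple[str, int]] = [("CDS", int(l)) for l in lengths]
    for cls, ln in extra:
        order.insert(int(rng.integers(0, len(order) + 1)), (cls, ln))
    gaps = rng.integers(20, 201, size=len(order))
    total = sum(ln for _, ln in order) + int(gaps.sum())
    if total > config.reference_length:
        raise CapacityError(
            f"features need {total} nt but reference is {config.reference_length} nt"
        )

    features: list[GenomicFeature] = []
    cursor = 1
    orf_idx = 0
    rna_idx = 0
    for (cls, ln), gap in zip(order, gaps):
        cursor += int(gap)
        start, end = cursor, cursor + ln - 1
        if cls == "CDS":
            orf_idx += 1
            fid = f"orf{orf_idx:04d}"
        else:
            rna_idx += 1
            fid = f"{cls.lower()}{rna_idx:02d}"
        features.append(
            GenomicFeature(
                feature_id=fid,
                reference=config.reference_name,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                feature_class=cls,
            )
        )
        cursor = end + 1
    annotation = GenomeAnnotation(features)

    orf_ids = [f.feature_id for f in annotation.protein_coding]
    idx_of = {fid: i for i, fid in enumerate(orf_ids)}
    for reg in config.regulons:
        missing = [m for m in reg.member_features if m not in idx_of]
        if missing:
            raise ValueError(
                f"regulon {reg.name!r} names unknown ORFs: {missing[:5]}"
            )

    law = config.baseline_abundance_law
    if law == "uniform":
        weights = np.ones(len(orf_ids))
    elif law.startswith("lognormal"):
        sigma = float(law.split(":", 1)[1]) if ":" in law else 1.0
        weights = rng.lognormal(mean=0.0, sigma=sigma, size=len(orf_ids))
    else:
        raise ValueError(f"unknown baseline abundance law {law!r}")
    for reg in config.regulons:
        for fid in reg.member_features:
            if reg.baseline_weight is not None:
                weights[idx_of[fid]] = reg.baseline_weight
            else:
                weights[idx_of[fid]] *= reg.baseline_scale

    abundances: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        vec = weights.copy()
        for reg in config.regulons:
            fac = reg.factors(cond)
            for fid, f in zip(reg.member_features, fac):
                vec[idx_of[fid]] *= f
        abundances[cond] = vec / vec.sum()

    truth = TruthTable(
        feature_ids=orf_ids,
        abundances=abundances,
        regulon_members={r.name: r.member_features for r in config.regulons},
    )
    return annotation, truth


def simulate_counts(
    truth: TruthTable,
    condition_id: str,
    depth: int,
    seed: int,
    replicate: int = 0,
    overdispersion: float | None = None,
) -> CountTable:
    """Draw a per-ORF count table at the given depth.

    Counts are multinomial over the condition's truth composition, or
    Dirichlet-multinomial when ``overdispersion`` (the Dirichlet
    concentration; smaller = noisier) is set. N equals the depth by
    construction; the same (seed, condition, replicate) always returns
    identical counts.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = truth.abundance_vector(condition_id)
    rng = _rng_for(seed, condition_id, replicate, "counts")
    if overdispersion is not None:
        alpha = np.maximum(overdispersion * p, 1e-12)
        p = rng.dirichlet(alpha)
    draws = rng.multinomial(depth, p)
    counts = dict(zip(truth.feature_ids, (int(c) for c in draws)))
    return CountTable(
        sample_id=f"{condition_id}_rep{replicate + 1}",
        counts=counts,
        total_mrna_counts=depth,
        filter_stats=FilterStats(depth, 0, 0, depth),
    )


def simulate_alignments(
    truth: TruthTable,
    condition_id: str,
    config: SimulationConfig,
    seed: int,
    replicate: int = 0,
    boundary_jitter: bool = False,
) -> list[AlignmentRecord]:
    """Draw reads as alignment records (fixed length, ungapped).

    Of ``config.depth`` reads, a binomial ``rrna_fraction`` share is placed
    in rRNA features and the rest in ORFs proportional to the condition's
    truth composition. Each read is uniform within its source feature
    (fully contained; with ``boundary_jitter`` it may hang over either end
    by up to read_length-1 nt, producing partial overlaps). A binomial
    ``non_unique_fraction`` share is flagged non-unique.
    """
    p = truth.abundance_vector(condition_id)
    rng = _rng_for(seed, condition_id, replicate, "alignments")
    read_len = config.read_length
    annotation_needed = truth.feature_ids
    n = config.depth

    # feature geometry comes from the regenerated genome for this config
    annotation, _ = build_genome(config)
    orf_feats = {f.feature_id: f for f in annotation.protein_coding}
    rrna_feats = [f for f in annotation.features if f.feature_class == "rRNA"]
    min_len = min(
        [orf_feats[fid].length for fid in annotation_needed]
        + [f.length for f in rrna_feats]
    )
    if read_len > min_len:
        raise ValueError(
            f"read length {read_len} exceeds the shortest target feature "
            f"({min_len} nt)"
        )

    n_rrna = rng.binomial(n, config.rrna_fraction) if config.rrna_fraction else 0
    n_mrna = n - n_rrna
    orf_draws = rng.multinomial(n_mrna, p)

    sources: list[GenomicFeature] = []
    for fid, k in zip(annotation_needed, orf_draws):
        sources.extend([orf_feats[fid]] * int(k))
    rrna_pick = rng.integers(0, len(rrna_feats), size=n_rrna)
    sources.extend(rrna_feats[i] for i in rrna_pick)

    starts = np.fromiter((f.start for f in sources), dtype=np.int64, count=n)
    ends = np.fromiter((f.end for f in sources), dtype=np.int64, count=n)
    if boundary_jitter:
        lo = np.maximum(starts - read_len + 1, 1)
        hi = ends  # start positions allowing >=1 nt overlap
    else:
        lo = starts
        hi = ends - read_len + 1
    pos = lo + (rng.random(n) * (hi - lo + 1)).astype(np.int64)
    non_unique = rng.random(n) < config.non_unique_fraction
    perm = rng.permutation(n)

    sample = f"{condition_id}_rep{replicate + 1}"
    records = [
        AlignmentRecord(
            read_id=f"{sample}_r{int(i):07d}",
            reference=config.reference_name,
            start=int(pos[i]),
            end=int(pos[i]) + read_len - 1,
            unique=not bool(non_unique[i]),
            strand="+",
        )
        for i in perm
    ]
    return records


def write_reference_fasta(config: SimulationConfig, path: str) -> None:
    """Random nucleotide reference matching the configured length, for SAM
    header consistency. Regenerable from (config, seed)."""
    rng = _rng_for(config.seed, "__genome__", 0, "sequence")
    alphabet = np.array(list("ACGT"))
    seq = rng.integers(0, 4, size=config.reference_length)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f">{config.reference_name}\n")
        for i in range(0, config.reference_length, 70):
            fh.write("".join(alphabet[seq[i : i + 70]]) + "\n")


def default_study_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """The packaged study scenario.

    Seven conditions mirror a two-experiment far-red-light design: a
    triplicated white-light control (WT_WL) and single libraries for
    far-red light (WT_FRL), erythromycin-supplemented white/far-red light
    (WT_WL_Em, WT_FRL_Em), and the regulator knockouts in far-red light
    (rfpB_FRL, rfpC_FRL, rfpA_FRL). Three regulons:

    * ``farlip_cluster`` — 20 genes, nearly silent at baseline, induced
      1e3- to 4.35e4-fold in WT_FRL, not induced in rfpB/rfpC, weakly
      (2-5x) in rfpA, and attenuated ~90% by erythromycin in far-red light;
    * ``pbp_psi_wl`` — 15 phycobiliprotein/photosystem-I-like genes,
      repressed to 5-50% of baseline in far-red light and repressed
      strongly (to 0.2-10%) by erythromycin;
    * ``em_response`` — 5 antibiotic-response genes induced 50- to
      670-fold by erythromycin.

    Keyword overrides (e.g. ``depth=...``, ``n_orfs=...``) replace config
    fields; regulon membership blocks are fixed to the first 40 ORFs.
    """
    farlip = [f"orf{i:04d}" for i in range(1, 21)]
    pbp = [f"orf{i:04d}" for i in range(21, 36)]
    em = [f"orf{i:04d}" for i in range(36, 41)]

    farlip_frl = [float(x) for x in np.geomspace(1e3, 4.35e4, len(farlip))]
    farlip_frl_em = [f * 0.1 for f in farlip_frl]
    rfpa_weak = [float(x) for x in np.geomspace(2.0, 5.0, len(farlip))]
    pbp_frl = [float(x) for x in np.geomspace(0.05, 0.5, len(pbp))]
    pbp_em = [float(x) for x in np.geomspace(0.002, 0.1, len(pbp))]
    em_up = [float(x) for x in np.geomspace(50.0, 670.0, len(em))]

    regulons = [
        RegulonSpec(
            name="farlip_cluster",
            member_features=farlip,
            baseline_weight=0.1,
            fold_factor_by_condition={
                "WT_FRL": farlip_frl,
                "WT_FRL_Em": farlip_frl_em,
                "rfpA_FRL": rfpa_weak,
                "rfpB_FRL": 1.0,
                "rfpC_FRL": 1.0,
            },
        ),
        RegulonSpec(
            name="pbp_psi_wl",
            member_features=pbp,
            fold_factor_by_condition={
                "WT_FRL": pbp_frl,
                "WT_FRL_Em": pbp_em,
                "WT_WL_Em": pbp_em,
                "rfpA_FRL": pbp_frl,
                "rfpB_FRL": pbp_frl,
                "rfpC_FRL": pbp_frl,
            },
        ),
        RegulonSpec(
            name="em_response",
            member_features=em,
            baseline_weight=0.05,
            fold_factor_by_condition={
                "WT_WL_Em": em_up,
                "WT_FRL_Em": em_up,
            },
        ),
    ]
    params = dict(
        n_orfs=1000,
        orf_length_range=(300, 3000),
        reference_length=2_000_000,
        regulons=regulons,
        baseline_abundance_law="lognormal:1.0",
        conditions={
            "WT_WL": 3,
            "WT_FRL": 1,
            "WT_WL_Em": 1,
            "WT_FRL_Em": 1,
            "rfpB_FRL": 1,
            "rfpC_FRL": 1,
            "rfpA_FRL": 1,
        },
        depth=2_000_000,
        rrna_fraction=0.05,
        non_unique_fraction=0.02,
        read_length=100,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)
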