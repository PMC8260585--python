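"""Synthetic communities with known ground truth.

Everything downstream of sampling — read recruitment, relative abundance,
imaging quantification, flow-cytometry integration and ploidy estimation —
is exercised here against communities whose cell densities, gene copy
numbers (ploidy) and sampling parameters are known exactly.  The module
emulates:

* a mixed bacterial community carrying a small diazotroph fraction spread
  over taxa and lifestyles (colonial filaments, diatom symbionts,
  free-living unicells, particle-associated heterotrophs);
* marker sequences (one nifH per diazotroph taxon, a recA for the bulk
  community) plus homologous outgroup decoys;
* shotgun reads drawn multinomially over markers with i.i.d. substitution
  errors, together with the exact latent per-gene counts used;
* net-sampled image detections, Poisson in the imaged subsample under the
  net / cod-end-dilution / subsampling scheme;
* noisy flow-cytometry totals for the bulk community.

Per-sample seeds are derived from a master seed by fixed arithmetic, so a
whole multi-sample campaign is reproducible from one integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .catalog import MarkerCatalog, MarkerSequence

_BASES = np.array(list("ACGT"))

DEPTH_LAYERS = ("SRF", "DCM", "MES")


class TruthValidationError(ValueError):
    """Raised when a community configuration violates an invariant."""


@dataclass(frozen=True)
class TaxonSpec:
    """Ground truth for one diazotroph taxon.

    density is cells per litre of seawater; ploidy is nifH copies per cell
    (values well above 1 are real — colonial filaments such as
    Trichodesmium carry several genome copies per cell); marker_length is
    the nifH reference length in bp.
    """

    label: str
    group: str
    density: float
    ploidy: float
    marker_length: int = 750
    lifestyle: str = "free-living"

    def __post_init__(self) -> None:
        if self.density < 0:
            raise TruthValidationError(f"{self.label}: density must be >= 0")
        if self.ploidy < 0:
            raise TruthValidationError(f"{self.label}: ploidy must be >= 0")
        if self.marker_length < 1:
            raise TruthValidationError(f"{self.label}: marker_length must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """A validated community: taxa plus bulk-community context.

    background_bacteria_density is the TOTAL bacterioplankton density
    (cells/L) carrying one recA per cell; the true diazotroph cell
    fraction is the summed taxon density over this total.
    """

    taxa: tuple[TaxonSpec, ...]
    background_bacteria_density: float
    outgroup_read_fraction: float = 0.01
    unassigned_read_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.taxa:
            raise TruthValidationError("at least one taxon is required")
        labels = [t.label for t in self.taxa]
        if len(labels) != len(set(labels)):
            raise TruthValidationError("taxon labels must be unique")
        if self.background_bacteria_density < 0:
            raise TruthValidationError("background_bacteria_density must be >= 0")
        for frac, name in (
            (self.outgroup_read_fraction, "outgroup_read_fraction"),
            (self.unassigned_read_fraction, "unassigned_read_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise TruthValidationError(f"{name} must lie in [0, 1]")
        if self.outgroup_read_fraction + self.unassigned_read_fraction >= 1.0:
            raise TruthValidationError(
                "outgroup_read_fraction + unassigned_read_fraction must be < 1"
            )

    @property
    def diazotroph_cell_fraction(self) -> float:
        """True Σ taxon density / total bacterioplankton density."""
        return sum(t.density for t in self.taxa) / self.background_bacteria_density

    def taxon(self, label: str) -> TaxonSpec:
        for t in self.taxa:
            if t.label == label:
                return t
        raise KeyError(label)


@dataclass(frozen=True)
class SampleSpec:
    """Sampling and sequencing parameters for one station/sample.

    Volumes follow the net-sampling scheme: V_seawater litres pass the
    plankton net, the cod end is diluted to codend_dilution_volume litres
    (3 L), a fixed_fraction (45/50) of a subsample is fixed, and Vi litres
    are imaged.  DNA_extracted (ng) may be left None and derived from the
    truth via :func:`consistent_dna_yield`.
    """

    sample_id: str
    V_seawater: float
    Vi: float
    total_reads: int
    codend_dilution_volume: float = 3.0
    fixed_fraction: float = 45.0 / 50.0
    DNA_extracted: float | None = None
    n_membranes: int = 1
    read_length: int = 100
    substitution_rate: float = 0.0
    seed: int = 0
    latitude: float = 0.0
    depth_layer: str = "SRF"
    size_fraction: str = "20-180"

    def __post_init__(self) -> None:
        for v, name in (
            (self.V_seawater, "V_seawater"),
            (self.Vi, "Vi"),
            (self.codend_dilution_volume, "codend_dilution_volume"),
        ):
            if v <= 0:
                raise TruthValidationError(f"{name} must be > 0")
        if not 0.0 < self.fixed_fraction <= 1.0:
            raise TruthValidationError("fixed_fraction must lie in (0, 1]")
        if self.total_reads <= 0:
            raise TruthValidationError("total_reads must be > 0")
        if self.read_length < 1:
            raise TruthValidationError("read_length must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise TruthValidationError("substitution_rate must lie in [0, 1)")
        if self.n_membranes < 1:
            raise TruthValidationError("n_membranes must be >= 1")
        if self.DNA_extracted is not None and self.DNA_extracted <= 0:
            raise TruthValidationError("DNA_extracted must be > 0 when given")
        if self.depth_layer not in DEPTH_LAYERS:
            raise TruthValidationError(f"depth_layer must be one of {DEPTH_LAYERS}")


def derive_seed(master_seed: int, index: int) -> int:
    """Per-sample seed from a master seed by fixed arithmetic (stays < 2^31)."""
    return (master_seed * 1_000_003 + 7919 * index) % (2**31)


def default_truth() -> SyntheticTruth:
    """Study-condition community: a tropical surface assemblage.

    Densities give a total diazotroph cell fraction of ~0.26% of a
    10^9 cells/L bacterioplankton community, inside the observed
    picoplankton range; ploidy defaults carry the reported copy numbers
    (Trichodesmium 5, Richelia/Calothrix 2, unicells ~1).
    """
    return SyntheticTruth(
        taxa=(
            TaxonSpec("Trichodesmium", "cyanobacteria", 2.4e4, 5.0, 750, "colonial"),
            TaxonSpec("Richelia_Calothrix", "cyanobacteria", 1.0e4, 2.0, 750, "symbiotic"),
            TaxonSpec("UCYN_A1", "cyanobacteria", 1.0e5, 1.0, 750, "symbiotic"),
            TaxonSpec("HBD_proteobacterium", "proteobacteria", 2.0e6, 1.0, 750, "particle"),
            TaxonSpec("Planctomycete_NCD", "planctomycetes", 5.0e5, 1.0, 750, "free-living"),
        ),
        background_bacteria_density=1.0e9,
        outgroup_read_fraction=0.01,
        unassigned_read_fraction=0.05,
    )


def generate_truth(config: dict | str, seed: int = 0) -> SyntheticTruth:
    """Build a validated :class:`SyntheticTruth` from a configuration.

    *config* is either a mapping or a path to a YAML file with keys
    ``taxa`` (list of mappings with ``label``, ``group``, ``density``,
    ``ploidy`` and optional ``marker_length``, ``lifestyle``),
    ``background_bacteria_density`` and the two read fractions.  The
    construction is a deterministic passthrough: identical config (and
    seed) always yields an identical truth.
    """
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    taxa = tuple(
        TaxonSpec(
            label=t["label"],
            group=t.get("group", "unknown"),
            density=float(t["density"]),
            ploidy=float(t["ploidy"]),
            marker_length=int(t.get("marker_length", 750)),
            lifestyle=t.get("lifestyle", "free-living"),
        )
        for t in config["taxa"]
    )
    return SyntheticTruth(
        taxa=taxa,
        background_bacteria_density=float(config["background_bacteria_density"]),
        outgroup_read_fraction=float(config.get("outgroup_read_fraction", 0.01)),
        unassigned_read_fraction=float(config.get("unassigned_read_fraction", 0.05)),
    )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def synthetic_catalog(
    truth: SyntheticTruth,
    seed: int = 0,
    recA_length: int = 1000,
    n_outgroups_nifH: int = 2,
    n_outgroups_recA: int = 1,
    outgroup_length: int = 900,
) -> MarkerCatalog:
    """A marker catalog matching *truth*: one nifH per taxon, one recA,
    plus homologous outgroup decoys (nifH-like chlorophyllide-reductase
    analogues, recA-like RAD51 analogues).

    Sequences are independent uniform-random nucleotides, which makes any
    two taxa far more than 15% divergent — deliberately easy to recruit
    correctly, so recovery failures point at the pipeline rather than the
    reference set.
    """
    rng = np.random.default_rng(seed)
    sequences: list[MarkerSequence] = []
    for t in truth.taxa:
        sequences.append(
            MarkerSequence(
                id=f"nifH|{t.label}",
                gene_class="nifH",
                taxon_label=t.label,
                taxonomic_group=t.group,
                sequence=_random_sequence(rng, t.marker_length),
            )
        )
    sequences.append(
        MarkerSequence(
            id="recA|bacteria",
            gene_class="recA",
            taxon_label="bacteria",
            taxonomic_group="bacteria",
            sequence=_random_sequence(rng, recA_length),
        )
    )
    for k in range(n_outgroups_nifH):
        sequences.append(
            MarkerSequence(
                id=f"outgroup_nifH|chlorophyllide_reductase_{k}",
                gene_class="outgroup_nifH_like",
                taxon_label=f"chlorophyllide_reductase_{k}",
                taxonomic_group="outgroup",
                sequence=_random_sequence(rng, outgroup_length),
            )
        )
    for k in range(n_outgroups_recA):
        sequences.append(
            MarkerSequence(
                id=f"outgroup_recA|RAD51_{k}",
                gene_class="outgroup_recA_like",
                taxon_label=f"RAD51_{k}",
                taxonomic_group="outgroup",
                sequence=_random_sequence(rng, outgroup_length),
            )
        )
    return MarkerCatalog(sequences)


def _marker_weights(truth: SyntheticTruth, catalog: MarkerCatalog, mode: str):
    """Per-source sampling weights for marker reads.

    ``copy`` mode: weight ∝ density × copies per cell (recA ∝ total
    density × 1), which makes the raw nifH/recA read-ratio estimator
    unbiased by construction.  ``length_weighted`` additionally multiplies
    by gene length, reproducing the per-base sampling bias a raw read
    ratio ignores.
    """
    if mode not in ("copy", "length_weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    sources: list[tuple[str, str, str]] = []  # (gene, taxon, reference id)
    weights: list[float] = []
    for t in truth.taxa:
        refs = catalog.for_taxon(t.label, "nifH")
        if not refs:
            raise KeyError(f"catalog has no nifH sequence for taxon {t.label!r}")
        w = t.density * t.ploidy
        if mode == "length_weighted":
            w *= t.marker_length
        sources.append(("nifH", t.label, refs[0].id))
        weights.append(w)
    recs = catalog.subset("recA")
    if not recs:
        raise KeyError("catalog has no recA sequence")
    w = truth.background_bacteria_density
    if mode == "length_weighted":
        w *= recs[0].length
    sources.append(("recA", "bacteria", recs[0].id))
    weights.append(w)
    return sources, np.asarray(weights, dtype=float)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """I.i.d. substitutions: each hit base moves to one of the other three."""
    if rate == 0.0:
        return seq
    hits = rng.random(seq.shape[0]) < rate
    if hits.any():
        seq = seq.copy()
        shift = rng.integers(1, 4, size=int(hits.sum()))
        seq[hits] = (seq[hits] + shift) % 4
    return seq


def simulate_metagenome(
    truth: SyntheticTruth,
    spec: SampleSpec,
    catalog: MarkerCatalog,
    mode: str = "copy",
    emit_reads: bool = True,
) -> tuple[pd.DataFrame | None, pd.DataFrame]:
    """Draw a shotgun read sample and return (reads, latent counts).

    ``spec.total_reads`` reads are drawn multinomially: the marker block
    (nifH per taxon + recA) receives probability
    1 − outgroup_read_fraction − unassigned_read_fraction split by
    :func:`_marker_weights`; outgroup reads come from the decoy sequences
    and unassigned reads are uniform-random sequence.  Reads are
    substrings of their source (the whole source when shorter than the
    read length) with i.i.d. substitutions at ``spec.substitution_rate``.

    The second frame holds the exact latent counts used (columns
    ``sample_id``, ``taxon``, ``gene``, ``reference_id``, ``count``) and
    always sums to ``total_reads``.  With ``emit_reads=False`` the first
    element is None — useful for large count-only simulations.
    """
    rng = np.random.default_rng(spec.seed)
    sources, weights = _marker_weights(truth, catalog, mode)

    o = truth.outgroup_read_fraction
    u = truth.unassigned_read_fraction
    outgroups = [s for s in catalog if s.is_outgroup]
    if o > 0 and not outgroups:
        raise KeyError("outgroup_read_fraction > 0 but catalog has no outgroup sequences")

    probs = list((1.0 - o - u) * weights / weights.sum())
    cells: list[tuple[str, str, str]] = list(sources)
    if o > 0:
        for og in outgroups:
            cells.append(("outgroup", og.taxon_label, og.id))
            probs.append(o / len(outgroups))
    if u > 0:
        cells.append(("unassigned", "none", "none"))
        probs.append(u)
    counts = rng.multinomial(spec.total_reads, np.asarray(probs))

    count_rows = [
        {
            "sample_id": spec.sample_id,
            "taxon": taxon,
            "gene": gene,
            "reference_id": ref,
            "count": int(c),
        }
        for (gene, taxon, ref), c in zip(cells, counts)
    ]
    counts_df = pd.DataFrame(count_rows)

    reads_df = None
    if emit_reads:
        from .alignment import encode

        rows = []
        k = 0
        for (gene, taxon, ref), c in zip(cells, counts):
            if c == 0:
                continue
            if gene == "unassigned":
                for _ in range(c):
                    seq = _random_sequence(rng, spec.read_length)
                    rows.append((f"{spec.sample_id}:r{k}", seq, gene, taxon, ref))
                    k += 1
                continue
            src = encode(catalog[ref].sequence)
            L = src.shape[0]
            starts = rng.integers(0, max(1, L - spec.read_length + 1), size=c)
            for s in starts:
                frag = src[s : s + spec.read_length]
                frag = _mutate(rng, frag, spec.substitution_rate)
                rows.append(
                    (f"{spec.sample_id}:r{k}", "".join(_BASES[frag]), gene, taxon, ref)
                )
                k += 1
        reads_df = pd.DataFrame(
            rows, columns=["read_id", "sequence", "source_gene", "source_taxon", "source_ref"]
        )
    return reads_df, counts_df


@dataclass(frozen=True)
class AxisModel:
    """Log-normal model for detected-object axes (µm).

    The major axis is log-normal around ``median_major_um`` with log-scale
    spread ``sigma_log``; the minor axis is the major axis times a uniform
    aspect ratio in [aspect_min, aspect_max], guaranteeing minor ≤ major.
    """

    median_major_um: float = 30.0
    sigma_log: float = 0.4
    aspect_min: float = 0.3
    aspect_max: float = 1.0

    def draw(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        major = np.exp(rng.normal(math.log(self.median_major_um), self.sigma_log, n))
        aspect = rng.uniform(self.aspect_min, self.aspect_max, n)
        return major, major * aspect


def concentration_factor_of(spec: SampleSpec) -> float:
    """Cf = (V_seawater / cod-end dilution volume) × fixed fraction."""
    return (spec.V_seawater / spec.codend_dilution_volume) * spec.fixed_fraction


def simulate_imaging(
    truth: SyntheticTruth,
    spec: SampleSpec,
    seed: int | None = None,
    axis_model: AxisModel | None = None,
    labels: list[str] | None = None,
    instrument: str = "confocal",
) -> pd.DataFrame:
    """Poisson image detections for the imaged subsample.

    Per taxon the detection count is Poisson(density × Vi × Cf) — the
    exact inverse of the abundance normalisation A = n/(Vi × Cf).  Axes
    are drawn from *axis_model*.  Returns an Ecotaxa-style frame with
    columns ``object_id``, ``sample_id``, ``label``, ``instrument``,
    ``major_um``, ``minor_um``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    am = axis_model or AxisModel()
    cf = concentration_factor_of(spec)
    rows = []
    for t in truth.taxa:
        if labels is not None and t.label not in labels:
            continue
        n = rng.poisson(t.density * spec.Vi * cf)
        major, minor = am.draw(rng, n)
        for i in range(n):
            rows.append(
                {
                    "object_id": f"{spec.sample_id}:{t.label}:{i}",
                    "sample_id": spec.sample_id,
                    "label": t.label,
                    "instrument": instrument,
                    "major_um": major[i],
                    "minor_um": minor[i],
                }
            )
    return pd.DataFrame(
        rows, columns=["object_id", "sample_id", "label", "instrument", "major_um", "minor_um"]
    )


def simulate_flow_cytometry(
    truth: SyntheticTruth,
    spec: SampleSpec,
    cv: float = 0.1,
    seed: int | None = None,
) -> float:
    """A noisy bulk bacterioplankton density (cells/L).

    Log-normal noise around background_bacteria_density with coefficient
    of variation *cv* (the log-normal mean equals the true density);
    cv = 0 returns the truth exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    bg = truth.background_bacteria_density
    if cv == 0.0:
        return bg
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(bg) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, math.sqrt(sigma2))))


def consistent_dna_yield(
    truth: SyntheticTruth,
    spec: SampleSpec,
    copies_per_ng_const: float,
) -> float:
    """DNA yield (ng per membrane) consistent with the copies-per-litre model.

    The copies-per-litre formula assumes a taxon's share of sequenced
    reads equals its nifH mass share of the extracted DNA.  In "copy"
    mode the expected read share of taxon t is
    (1 − o − u) · density·ploidy / W with W = Σ density·ploidy + background,
    so the unique yield making the estimator exact in expectation is

        DNA = W · V_seawater / (3 · n) / (copies_per_ng · (1 − o − u)),

    i.e. every marker copy in the membrane-equivalent seawater volume is
    booked at the mass of one nifH-length amplicon.
    """
    W = sum(t.density * t.ploidy for t in truth.taxa) + truth.background_bacteria_density
    frac = 1.0 - truth.outgroup_read_fraction - truth.unassigned_read_fraction
    vol = spec.V_seawater / (spec.codend_dilution_volume * spec.n_membranes)
    return W * vol / (copies_per_ng_const * frac)


def with_seed(spec: SampleSpec, seed: int) -> SampleSpec:
    """A copy of *spec* with a different seed (convenience for seed sweeps)."""
    return replace(spec, seed=seed)
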