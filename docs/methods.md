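# Methods

## Scope and model

diazoquant quantifies marine diazotrophs by combining three observation
channels that measure different things on different scales:

* **metagenomes** measure *gene copies* — the recruited read ratio
  nifH/recA estimates the diazotroph share of gene copies in the
  bacterioplankton, which equals the cell share only if both markers are
  single-copy per cell;
* **imaging** measures *cells* (or filaments/colonies, depending on the
  label) per litre of original seawater, after undoing the net
  concentration;
* **flow cytometry** measures the *bulk* bacterioplankton density,
  anchoring relative estimates to an absolute scale.

The tension between the first two channels is the point: dividing gene
copies per litre by cells per litre yields the per-cell copy number
(ploidy), which quantifies exactly how far the single-copy assumption is
violated for each taxon.

## Read recruitment

Every read is aligned to every catalog sequence (markers and outgroup
decoys in one competitive pool) with an affine-gap Smith–Waterman
(Gotoh) algorithm: match +1, mismatch −1, gap open −2, gap extend −1; a
gap of length k costs open + (k−1)·extend; `N` scores as a mismatch and
never counts as an identity match. Identity is matches over alignment
columns (gaps included), coverage is aligned read bases over read
length. This is a deliberate desk-scale replacement for a heuristic
mapper: exact, convention-complete, and checkable against a brute-force
dynamic-programming oracle, at the cost of not scaling past ~10⁴ reads ×
~10² references (the numba kernel handles that comfortably; the test
suite's largest alignment problem is 200 reads × 8 references).

Assignment is best-hit-first, filter-second: the single best reference
is chosen by score, then identity, then alignment length, then smallest
reference id; the identity/coverage gates are applied to that hit only.
The alternative reading (drop gated hits, then take the best survivor)
would let a *stricter* identity threshold *increase* some reference's
count by reassignment, violating the monotonicity property the filter
set is meant to have. Reads whose best hit is an outgroup are excluded
from marker counts; assigned + outgroup + unassigned always equals the
input read count.

The complexity gate interprets the two undocumented wrapper thresholds
as: fail when the most frequent nucleotide exceeds `complexity_percent`
(default 75%) of the read, or when the longest mononucleotide run is at
least `complexity_number` (default 30) bases. Both are exposed as
parameters since the original semantics are not published.

Multi-mapping across redundant catalog entries is resolved by
deterministic best-hit (no fractional counting); mates are treated as
independent single-end observations.

## Abundance estimators

`diazotroph_fraction` is the raw ratio 100·nifH/recA with no gene-length
correction — matching the published estimator. The bias this ignores is
real: when reads are sampled per base (longer genes catch more reads),
the estimator converges to (L_nifH/L_recA) × true fraction. Rather than
correcting it, the simulator exposes it: "copy" mode draws reads
proportional to copy numbers (ratio unbiased by construction),
"length_weighted" mode draws proportional to copies × length, and the
package asserts the measured bias equals the length ratio. Samples with
recA = 0 and nifH > 0 are excluded as undefined rather than imputed;
nifH = 0 is a valid "absent" observation, not an error.

`absolute_ncd_density` multiplies a flow-cytometry bulk density by the
fraction; `ncd_biovolume` applies a literature-informed mean NCD cell
volume of 1 µm³ (exposed as a parameter).

## Imaging quantification

Confocal net samples: A = n/(Vi·Cf) with Cf = (V_seawater/3 L)·(45/50).
The 3 L is the cod-end dilution volume and 45/50 the fixed aliquot
fraction; both are parameters with those defaults. UVP5 detections are
normalised by the calibrated in-situ imaged volume per cast (a required
input — the package does not reconstruct it from frame counts).

Biovolume uses the two measured axes and must invent the third: the
default is a prolate spheroid (third axis = minor, V = π/6·a·b²), with
an oblate alternative (π/6·a²·b) exposed, since detection tables carry
only two axes. Counting units are preserved per label — symbiotic cells,
filaments and colonies are never summed across units.

## Ploidy

copies/ng = N_A/(L · m_bp · 10⁹) with m_bp = 660 g/mol, giving
1.2166 × 10⁹ at 750 bp; `constant_mode="published"` pins the published
rounded constant 1.21 × 10⁹ instead for exact replication. The
copies-per-litre formula assumes 100% extraction efficiency and equates
a taxon's read share with its nifH mass share of the extract.

Ploidy is reported as copies_per_L / cells_per_L. The source material
describes the division in the opposite direction in one sentence, but
only copies-per-cell is consistent with the reported magnitudes
(colonial filaments ≈ 5, symbionts ≈ 2); the package treats the sentence
as a wording slip and implements copies per cell. Medians use the
midpoint convention for even counts; cross-taxon ratios are computed
only within samples where both taxa have defined estimates, and pairing
requires identical sample ids (no spatial interpolation).

## Synthetic data: what it emulates and what it does not

The generator's defaults describe a tropical surface assemblage: a
10⁹ cells/L bacterioplankton background carrying five diazotroph taxa
(colonial filaments at 2.4 × 10⁴ cells/L with ploidy 5, diatom symbionts
at 10⁴ with ploidy 2, a unicellular cyanobacterial symbiont at 10⁵, and
two NCDs at 2 × 10⁶ and 5 × 10⁵, all ploidy 1) — a total cell fraction
of ~0.26%, inside the observed picoplankton range, with copy numbers at
the reported field medians. Reads are multinomial over marker sequences
only (plus a 1% outgroup and 5% random-sequence unassigned fraction):
genome-wide shotgun realism (GC bias, duplicates, quality profiles,
indels by default) is deliberately out of scope because only
marker-mapped reads matter downstream and a substitution-only error
model keeps identity accounting exact for oracle tests. Marker
sequences are independent uniform-random nucleotides, i.e. far more
divergent than real nifH variants; recruitment recall measured here
therefore bounds pipeline correctness, not real-world taxonomic
resolution among close relatives.

Image detections are Poisson in the imaged subsample — the exact inverse
of the abundance normalisation — with log-normal major axes and uniform
aspect ratios; there is no segmentation error, classification error or
chain/colony structure, so imaging tests validate the volumetric
arithmetic and Poisson statistics, not computer-vision performance.
Flow-cytometry noise is log-normal with the mean pinned to the true
density (mean-preserving, so integration tests are recovery tests).

`consistent_dna_yield` closes the loop for ploidy recovery: it returns
the unique membrane DNA mass under which the copies-per-litre formula's
mass-share assumption holds exactly in "copy" mode
(DNA = W·V/(3n)/(copies_per_ng·(1−o−u)), W = Σ density·ploidy +
background — every marker copy booked at the mass of one 750 bp
amplicon). Real extracts contain mostly non-marker DNA; the synthetic
yield is an accounting device, not a realistic nanogram figure.

Per-sample seeds derive from a master seed by fixed arithmetic
(`derive_seed`), all below 2³¹; every generator is bit-reproducible
under a fixed seed.

## Numerical and test-design choices

* Alignment tie-breaks are fully specified (traceback prefers diagonal,
  then gap-in-reference, then gap-in-read; start cell is the
  smallest-index maximum) so the implementation and the independent
  plain-Python oracle agree read-for-read, not just on scores.
* Statistical recovery tests fix their seeds and use 2-SE bands around
  unbiased estimators; problem sizes (10⁵–10⁶ reads, hundreds of
  expected detections, 10–100 seeds) are chosen so the Monte-Carlo
  standard error is several times smaller than the asserted tolerance.
* Spearman p-values are permutation-based (10⁴ label permutations,
  seeded, add-one estimator), mirroring the uncorrected one-sided
  reporting convention; asymptotic p-values are not used.
* Hotspots are operationalised as strictly exceeding the q-quantile
  (default 0.9) of non-zero abundances — the underlying notion is
  descriptive, and the quantile is exposed.
* Latitude bands are half-open [lo, lo+w) anchored at −90°, so stations
  partition exactly.

## Known limitations

* Ploidy is estimated only for taxa quantifiable by both channels in
  the same sample; no values are produced for NCDs or unicellular
  cyanobacteria, whose imaging counterparts are absent.
* The recruiter is not a drop-in for a production mapper at survey
  scale, and translated (protein-space) search is not implemented.
* The deposited per-sample field table needed to re-derive the published
  ploidy medians from real data is not redistributable here; the
  corresponding check runs only when that table is supplied (see
  `tests/test_acceptance.py`).
* Ordination (NMDS), environmental vector fitting and GAM smoothing are
  intentionally left to vegan/mgcv-class tools; the package exports the
  distance matrices they consume.
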