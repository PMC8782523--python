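# Methods

## Scope and model

`parkshift` summarizes pre-computed species-distribution-model output;
it does not fit SDMs. Inputs are per-species, per-season suitability
grids in [0, 1] for a baseline period and one warming scenario, a
species-specific occurrence threshold, park masks on the same grid, a
five-trait table, and optional expert-review exclusions. All surfaces of
a dataset must share one grid; no resampling or reprojection is
performed, because a resampling policy would itself change the analysis.

## Change classification

Presence in a period is suitability ≥ threshold, with the threshold
inclusive. The five categories partition all finite (baseline, scenario)
pairs; a sixth artifact class, `absent`, covers cells below threshold in
both periods. Percent change is computed in double precision with no
rounding before the interval test. The published category bounds overlap
at ±25%; here *stable* is closed [−25, +25] and *worsening* and
*improving* are open at ±25, so boundary cells resolve to the
no-change class.

`absent` cells are excluded from the park majority vote: structural
zeros in a large park would otherwise outvote every occupied cell and no
wide-ranging species would ever receive a projection. A species whose
park cells are all `absent` gets no projection there and joins neither
assemblage. Majority ties are broken by a fixed priority —
extirpation > colonisation > worsening > improving > stable —
deterministic and biased toward flagging change, which is the
conservative direction for management triage; the order is a config
field. Grid convention: row-major 0-based cell indices; park masks are
explicit cell sets with no partial-cell weighting.

Review filtering operates at species×park×season granularity. An
`unconfirmed_baseline` flag drops a record whose majority implies
baseline presence; an `improbable_colonisation` flag drops a record
whose majority is potential colonisation; incompatible flags warn and
remove nothing. Removal fractions per flag class are reported.

## Assemblage metrics

Sørensen turnover is 1 − 2|A∩B|/(|A|+|B|); Jaccard turnover
1 − |A∩B|/|A∪B| is computed alongside and always ≥ the Sørensen value.
Turnover is undefined (and the park/season omitted with a warning) when
both assemblages are empty.

Trend groups cut the colonisation-proportion vs extirpation-proportion
plane by per-axis quartiles (numpy linear interpolation). Denominators:
colonisations are scaled by future richness, extirpations by current
richness — configurable in code, since the choice is a convention.
Sector rules: both proportions strictly above their upper quartile →
high turnover; exactly one → high potential colonisation/extirpation;
both strictly below their median → low change; the remainder, including
fully degenerate distributions where no park clears a strict cut, →
intermediate change. Strict inequalities are what make the five sectors
exhaustive and mutually exclusive even when many parks tie at a
quartile. Parks with no colonisations or extirpations are still
classified. At least five parks with non-empty assemblages are required.

Regional summaries report mean ± SE (sample SD/√n) per region and
season plus a national row; single-park regions print a bare mean
(SE = NaN).

## Functional trait space

Gower distance averages five per-trait contributions: 0/1 mismatch for
the four unordered traits and a rank difference scaled by the observed
rank range for ordered relative size, which is encoded as equally spaced
ranks. A single-level trait contributes 0 with a warning. Gower
matrices are generally non-Euclidean, so dissimilarities are
square-root-transformed before PCoA (the standard correction); if fewer
than `n_axes` positive eigenvalues remain the build fails loudly rather
than silently shrinking the space. The correction is a keyword
(`correction=None` embeds already-Euclidean distances exactly, which the
tests exploit as an oracle).

Space quality is the mean squared deviation between the input
dissimilarities and the embedded Euclidean distances after rescaling the
latter by the least-squares factor Σxy/Σy²; an exact embedding scores 0
and adding axes does not increase it in practice.

The pool for each season is every species appearing in any (non-excluded)
park's current or future assemblage that season; current and future
indices therefore live in one common space. Six axes are the default —
few enough for stable convex hulls, enough for a good embedding. FRic is
the assemblage hull volume over the pool hull volume (scipy/Qhull);
assemblages with fewer than n_axes + 1 affinely independent members are
flagged undefined rather than zero-filled. FDis uses the unweighted
(presence–absence) centroid and is scaled by `pool_max_distance / 2`, the
dispersion of the pool's two most distant species; the scaled value is
deliberately not clamped — an equilateral triangle with side equal to the
pool diameter scores 2/√3 ≈ 1.155. Restrictedness is occupied parks over
total parks, per period, computed only for species present somewhere in
both periods (the others carry an uninformative 0 in one period and are
dropped with a warning); the direction is 1 = present everywhere.
Parks excluded from functional analyses (e.g. known trait outliers) are
listed in config, not hard-coded.

## Model II major-axis regression

Both variables are the same index measured with error, so the symmetric
major axis replaces OLS. The slope CI uses the angle bound
H = t²_{α/2,n−2}/((λ₁/λ₂ + λ₂/λ₁ − 2)(n − 2)) with limits
tan(atan b ± atan √(H/(1−H))); when the angle interval crosses the
vertical the CI wraps through infinity, which is recorded explicitly
(`slope_ci_wraps`) instead of being clipped. The intercept CI is
propagated through the sample means from the slope limits. The
permutation test permutes y against x and is two-tailed on |r|
(no directional hypothesis), p = (1 + hits)/(n_perm + 1). Departure
from the 1:1 null is judged by CI exclusion of slope 1 or intercept 0,
and both the permutation p and the CI-based flag are reported, because a
permutation of y tests association rather than the identity slope
itself.

## Synthetic landscapes

The generator emulates the statistical structure of continental SDM
output on a desk-scale grid: suitability is a Gaussian response
exp(−(g−μᵢ)²/2w²) to a purely latitudinal gradient g (row index), with
per-species optima μᵢ spread across rows and jittered per season, plus
i.i.d. Gaussian noise clipped to [0, 1]. The warming scenario displaces
the gradient northward by `shift_cells` rows, so the scenario surface at
row r reproduces the baseline at row r − k — colonisation at the leading
edge, extirpation at the trailing edge. Parks are disjoint axis-aligned
rectangles (unambiguous masks with no geometry dependencies); all
synthetic species share one threshold (simpler ground truth; the
pipeline itself reads per-species thresholds from input metadata).
Review flags are drawn at the screening intensities of a real expert
review: 17% of baseline-present records flagged unconfirmed and 3.2% of
colonisation records flagged improbable.

Defaults: 40×30 grid, 30 species, 6 parks of 4×4 cells, shift 4 rows,
niche breadth 6 rows, noise SD 0.02, threshold 0.3. These sizes keep a
full run near-instant while leaving every stage non-trivial (parks
straddle range edges; pools exceed the 6-axis hull requirement).

What the generator does not emulate: spatial noise autocorrelation,
longitudinal or topographic gradients, species interactions, range-size
asymmetries, GCM-ensemble disagreement, or real park geometry. Tests
passing on these landscapes validate the bookkeeping and the
mathematics, not the ecological realism of any particular projection.

A brute-force oracle (independent per-cell enumeration with its own
scalar logic) recomputes park categories and presence sets; the test
suite requires exact agreement with the pipeline on randomized
landscapes, and cross-checks Gower against `cluster::daisy`, Sørensen
against `vegan`, and PCoA against scikit-bio.

## Numerical choices and degenerate inputs

- Eigenvalues below 1e−10 count as non-positive in PCoA.
- Qhull degeneracies (coplanar assemblages) surface as
  `undefined_reason` flags, never silent zeros.
- MA regression refuses constant variables, n < 3, and isotropic
  scatter (s_xy = 0, s_xx = s_yy, no preferred axis).
- Equal (config, seed) reproduces every output byte-for-byte; the run
  report records the config hash, seed, per-stage counts, removal
  fractions, warnings and per-file SHA-256 checksums.

## Known limitations

- Single scenario and single baseline per run; multi-scenario ensembles
  are out of scope.
- Presence-absence only; no abundance weighting, functional evenness or
  divergence, and no trait imputation.
- The trend-sector conventions and proportion denominators are
  documented choices; other conventions are defensible and would shift
  group membership near the cuts.
- Restrictedness follows the 1-means-ubiquitous direction used in the
  park-assemblage literature, which inverts the restriction index some
  functional-rarity tools report.
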