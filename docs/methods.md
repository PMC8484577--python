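# Methods

## The analysis problem

In a marker-assisted backcrossing program a target allele (here an
EMS-induced point mutation) is moved from a donor line into an elite
recurrent parent. Each generation has two selection steps: *foreground*
selection keeps the progeny that carry the target allele (heterozygous,
since the mutation is introgressed through repeated crossing to the
recurrent parent), and *background* selection keeps, among the
carriers, the plants whose genome is most like the recurrent parent.
`mabc` implements both steps for SNP-array genotypes plus the marker QC
in front of them and a PCA structure check, and ships a simulator that
generates populations whose true ancestry is known exactly, so every
statistic can be validated against analytic expectations.

## Genome-share statistic

Genotypes at markers with different fixed parental alleles are recoded
A (homozygous recurrent), H (heterozygous), B (homozygous donor). A
plant's recurrent-parent genome share is

    share_R = (2 n_A + n_H) / (2 (n_A + n_H + n_B)) * 100 ,

the percentage of its scored alleles inherited from the recurrent
parent; share_D is defined symmetrically with n_B.

Handling of missing data is the one genuinely open choice here: we
exclude missing calls from the denominator ("total number of alleles" =
2 × scored markers). This is the only convention under which
share_R + share_D = 100 holds identically, and it makes the statistic
invariant under marker duplication and permutation (both are tested).
B calls in a BC1 are impossible without genotyping error; they are kept
in the formula but counted and logged as probable errors.

Expected shares are closed-form: each backcross to the recurrent parent
halves the expected donor fraction, so after t backcrosses
E[share_R] = 100 (1 − (1/2)^(t+1)) — 75 % in BC1, 87.5 % in BC2 — and an
F1 × F1 double hybrid has E[share_R] = 50 %. The per-chromosome variant
of the statistic (the numbers behind a graphical genotype) uses the same
formula restricted to one chromosome's markers; chromosomes with no
scored marker are reported as undefined, never as 0.

## Foreground selection and segregation tests

A BC1 carrier is heterozygous at the single target locus; a double-
hybrid carrier is heterozygous at both loci. Samples with a missing
call at a target locus are reported separately and excluded from test
denominators. Counts are tested against the expected ratio with the
plain Pearson chi-square statistic (no continuity correction; p-value
from the chi-square upper tail, delegated to scipy). The BC1 test is
carriers : non-carriers vs 1:1. The double-hybrid test uses the four
joint classes het/het, het/hom, hom/het, hom/hom, where "hom" is any
homozygote at that locus: in a real program the two F1 parents carry
different mutant loci, so "hom" can only be the wild-type homozygote and
the classes segregate 1:1:1:1; in the simulator both F1s descend from
one donor genome, each locus segregates 1:2:1, but het : non-het is
still 1:1 per locus, so the same four classes remain 1:1:1:1 and one
classifier serves both settings.

## Marker QC cascade

Three filters run in fixed order, each reporting the markers it
removed: (1) *functional* markers, a per-marker missing-data threshold
defaulting to 0 (complete data only), exposed as a fraction for noisier
real data; (2) MAF filter, computed over all non-missing calls of the
full matrix (parents included), keeping markers with MAF ≥ 0.001 —
inclusive at the bound, and monomorphic markers (MAF = 0) are always
removed, so the zero-threshold filter removes exactly the monomorphic
markers; (3) parent-polymorphism filter keeping markers at which the
two parents carry different homozygous genotypes — a heterozygous or
missing parent call makes a marker uncodable in ABH terms, so it is
dropped rather than half-coded. The cascade counts are monotone by
construction and the filters commute when no marker triggers two of
them.

## Simulator

Meiosis uses the Haldane model: per chromosome the crossover count is
Poisson with mean equal to the map length in Morgans, crossover
positions are uniform, the starting strand is a fair coin, and there is
no interference and no obligate chiasma. This is the standard
closed-form-testable choice; the recombination fraction between two
positions d Morgans apart is r = ½(1 − e^(−2d)), which the tests verify
by Monte Carlo. Crossovers falling between regions of identical founder
origin leave no breakpoint, so segment lists always alternate founders
and tile [0, L] exactly — an invariant property-tested across seeds.

The default genome emulates *B. napus*: 19 chromosomes A01–A10/C01–C09,
100 cM each, physical lengths summing to ~1.13 Gbp (so a 6,887-marker
panel has the realistic density of ~6.09 markers/Mbp). Marker panels
place markers uniformly on the genetic map with an affine cM→bp map per
chromosome, used only for reporting. Both founders are fully inbred and
every panel marker is polymorphic between them (recurrent → ref,
donor → alt by default), emulating the informative subset of an array.

Populations: BC1 progeny are drawn from a single internally built F1
crossed to the recurrent parent; F1 × F1 progeny from one pair of
independently built F1s. Foreground conditioning (progeny heterozygous
for the donor allele at every target locus) is enforced by rejection
sampling — exact, and the acceptance probability is at least 1/4 per
scheme, so cost is bounded. Genotyping noise: with probability
`error_rate` a true call is replaced by a uniformly random non-missing
genotype, then with probability `missing_rate` a call is masked; errors
are applied before missingness. Both default to 0, which keeps the
analytic expectations exact. All randomness flows through one
`numpy.random.Generator` passed explicitly; identical seeds give
bit-identical populations, genotype matrices and pipeline outputs.

What the simulator deliberately does not emulate: crossover
interference (Kosambi etc.), sex-specific maps, homoeologous pairing of
the allotetraploid genome, segregation distortion, and any phenotypic
selection. Passing tests therefore validate the statistics under clean
Mendelian segregation with map-uniform markers; on real data, array
artifacts, distorted regions and uneven marker coverage will add noise
the tests do not probe. One observation from real double-hybrid
programs — mean recurrent shares a few points above 50 % — is *not*
reproduced by design: extra meiotic generations add recombination but do
not move the expectation, so the simulator keeps E[share] = 50 %.

## Validation scale and numerical choices

The test suite validates the expectations at study scale chosen to keep
Monte-Carlo error well inside the asserted tolerances: 2,000 plants ×
5,000 markers for the 75 %/50 % mean-share checks (±0.5), 200 plants for
the marker-vs-truth agreement (mean absolute error < 1 point,
correlation > 0.99), 2,000 replicate populations of n = 100 for the
size of the 1:1 chi-square test (rejection rate in [0.03, 0.07] at
α = 0.05; the exact binomial rejection probability at n = 100 is
0.0569), and 1,500 plants for the BC2 87.5 % check. `scripts/
acceptance.py` re-simulates the first three from scratch with a
user-supplied seed.

Other numerical conventions: markers exactly on a segment boundary take
the right-hand segment (a measure-zero event); PCA is an SVD of the
column-centered dosage matrix (equivalent, up to scale, to the
genetic-relationship-matrix eigendecomposition common SNP-PCA tools
use), with missing dosages mean-imputed and component signs fixed by
making each component's largest-magnitude loading positive so fixtures
are stable; report percentages are rounded to one decimal place only at
the output layer, never internally; "plants above expectation" uses a
strict inequality. VCF I/O is 1-based and unphased; genetic positions
travel in a side marker-map CSV rather than VCF INFO fields to keep the
VCF standard-conformant; phase exists only in the simulator's
ancestry-segments file.
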