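# Methods

## Coordinate conventions

Primer positions use the ATG-anchored convention: +1 is the A of the
start codon, −1 the base immediately 5′ of it; there is no coordinate 0.
Internally all operations work on 0-based half-open sequence indices;
labels are presentation only. The fragment length printed in an assay
name is reproduced by plain subtraction of the forward from the reverse
label. This convention is slightly inconsistent for amplicons that do
not straddle the ATG (an inclusive span would be r − f + 1), but it is
the convention the shipped validated panel follows for 8 of its 9
complete rows, so the designer generates reverse labels as
`forward label + amplicon length` to keep `label_len == amplicon_len`
exact. The one panel row whose printed length disagrees with its labels
by 12 bp (the HLA-B long-range assay) is flagged by `fixtures_check`
and deliberately not "fixed".

## Discriminating positions and ARMS design

A discriminating position for target allele *t* is an aligned column
where *t*'s base differs from the base of **every** other allele in the
database. The comparison set defaults to all loci, not just the
target's own locus, because HLA-A/-B/-C paralogs are similar enough
that a within-locus-unique site can still prime on another locus; a
`within_locus` switch restricts the scan. Columns containing a gap in
any compared sequence are excluded (inputs are assumed pre-aligned or
equal-length ungapped cDNAs; no aligner is bundled).

The designer enumerates, for each discriminating site, primers whose 3′
terminal base sits on the site (forward and reverse orientation), all
lengths in `len_range`, all partner placements giving amplicons within
bounds, then filters on Tm and finally on cross-reactivity. Exactly one
3′ base is required to match (`three_prime_k = 1`, configurable upward
since single-base 3′ discrimination is often leaky in practice).
Ranking is deterministic: summed |Tm − target| over both primers, then
distance of the amplicon from the middle of the allowed window, then
lexicographic sequences; the top `max_pairs` (default 10) are returned.

`validate_pair` re-derives every constraint — lengths, Tms, amplicon by
exact-match search, 3′ discrimination by a brute-force column scan,
cross-reactivity by a plain-Python binding scan — sharing no code with
the enumerator, so designer soundness is checked by a genuinely
independent route.

## In-silico PCR model

A primer is predicted to bind and extend where it matches the template
with zero mismatches in its 3′-terminal `three_prime_k` bases and at
most `max_internal_mismatches` (default 2) elsewhere; a product is
emitted for every convergent forward/reverse site pair whose size falls
in `product_window` (default 50–2000 bp). This is deliberately
conservative for specificity screening: tolerating internal mismatches
makes near-paralog sites count as potential products unless the 3′ rule
blocks them. The engine is exhaustively tested against a brute-force
all-offsets oracle.

## Melting temperature

Unified nearest-neighbor thermodynamics (Allawi & SantaLucia 1997;
SantaLucia 1998, PNAS 95:1460), with the parameter table frozen in
`data/nn_unified.json`: Tm = ΔH / (ΔS + R·ln(C_T/4)) − 273.15 with the
entropic salt correction 0.368·(N−1)·ln[Na+]. Default conditions are
50 mM monovalent salt and 500 nM total primer. The implementation is
cross-checked in the tests against Biopython's independent evaluation
of the same published table, and one validated-assay primer's Tm is
frozen as an oracle value computed before the implementation existed.

Default design targets are the wet-lab protocol values (66 ± 2 °C,
21-mers, 70–120 bp). Note that 66 °C reflects the hotter Tm scale of
the commercial design software the protocol used; under this NN model
at default salt, random 21-mers at the synthetic generator's 62 % GC
melt around 61–62 °C, so the synthetic design tests use a 62 ± 2.5 °C
window. The constraint set is an explicit parameter everywhere.

## Locus-specific long-range design

Primers must lie in windows identical across all alleles of the locus
(so one assay amplifies them all) and are screened by in-silico PCR
against every allele of the other loci. The amplicon must begin before
the first and end after the last exon–exon junction of the locus's exon
model; `SpliceCheckResult` reports the covered junctions and, for each
exon lying wholly between the primer footprints, the product size an
exon-skipping variant would give (always shorter than full length).
Default long-range bounds are 1000–1200 bp.

## Absolute qPCR quantification

Standard curves are ordinary least squares of CT on log10(copies) over
a plasmid dilution series (≥4 distinct levels required; the shipped
scenario uses six 10-fold dilutions from 2×10⁻² ng/µL, 5 µL per
reaction, 4031 bp plasmid). Copies are derived from mass via
N_A/(size·650 g·mol⁻¹·bp⁻¹). Efficiency follows Pfaffl,
E = 10^(−1/slope); QC uses a hard floor of 1.92 and a warning band
below 1.96 (both configurable) — warnings never abort. Technical
replicates are averaged on the CT scale before inversion. Ratios are
target copies over reference-gene copies in the same sample; ratios
from independent experiments combine as a geometric mean; kinetics are
folds relative to the unstimulated timepoint. Zero or negative inputs
raise rather than being imputed. There is no ΔΔCT relative-only mode
and no inter-plate calibrator (curves are expected on every plate).

## Flow cytometry calibration and scales

Bead calibration is least squares of log10(ABC) on log10(MFI) (≥4 bead
levels; the simulated panel uses five levels from 4 700 to 440 000 IgG
per bead, spanning the QIFIKIT range). ABC estimation inverts the fit;
no isotype subtraction is applied before ABC (the semi-quantitative
scale alone uses the isotype ratio). The ordinal scale is a fixed step
function of specific/isotype MFI: ≤3 → "−", <10 → "+/−", ≥10 → "1+",
≥30 → "2+", ≥50 → "3+", ≥100 → "4+", with the boundary at exactly 3
graded "−" (the bins are taken literally from their definition).

Fold values are presentation-rounded: the quotient is taken to one
decimal, and folds ≥10 are then reported as integers (so 39.4995 is
quoted as 39.5 → 40, 16.92 as 16.9 → 17); the raw quotient is available
via `rounding="none"`.

## CDC scoring

Percent dead is 100·red/(red+green); wells are averaged unweighted
(well-level cell counts vary little and no weighting is standard); the
typing call is positive strictly above the 50 % threshold. Wells under
200 counted cells set a flag but stay in the average. The AB-serum
background is reported alongside every call and only subtracted when
explicitly requested.

## Synthetic data

The generators emulate the *structural* properties the pipeline needs,
not real HLA polymorphism statistics. Allele families: loci are drawn
independently (cross-locus divergence ≈ 75 %, far above the within-locus
SNP rate of 0.5 %), GC content 0.62 (typical of HLA class I cDNA), ATG
at offset 60 with a 45 nt 3′UTR, and an exon model partitioning the
coding region (default 8 exons, ≥30 nt each). Each allele receives one
engineered column at which it differs from *every* other record — a
guaranteed discriminating site recorded in the truth sidecar; random
SNPs may add further discriminating columns, so exact-recovery tests
use `snp_rate = 0`.

qPCR wells, bead panels, cell MFIs and CDC counts are drawn from
exactly the models the fitting code assumes (Gaussian CT noise,
log-normal MFI noise, binomial counts), with per-target curve
parameters drawn in the accepted efficiency range (slopes −3.45 to
−3.33) and the default scenario's constitutive ratios, fold-inductions
(8.9–41.8 at 72 h, log-fractional rise 0/0.6/0.85/1.0 over
0/24/48/72 h), ABC values (204 370 / 12 076 / 5 174 constitutively) and
kill fractions (0.96/0.28/0.09) mirroring the validated panel.
Passing recovery tests therefore demonstrates correct inversion of the
stated models under realistic noise, not robustness to model
misspecification (no PCR inhibition, no bead saturation, no gating
artefacts).

A master seed is split into fixed named sub-streams (alleles=1, qpcr=2,
beads=3, cells=4, cdc=5) via `SeedSequence([seed, id])`, so adding one
generator never perturbs another's draws and regeneration is
byte-identical.

## Problem sizes and numerical choices

The designer-soundness suite runs 100 seeded families of 2 loci × 3
alleles × 800 nt — large enough that Tm, amplicon and cross-reactivity
constraints all bind, small enough to validate every emitted pair with
the brute-force checker. Oracle equality for in-silico PCR is checked
exhaustively on random instances of 300–1000 nt. Parameter-recovery
suites use 200 curve replicates at σ_CT = 0.1, 50 bead panels at 5 %
CV, and 500 binomial CDC runs (95 % Wald interval on ~1200 pooled
cells). Degenerate inputs (gap columns, single-record databases,
identical twin alleles, empty wells) return typed results or raise with
the offending record named; ties in design ranking are broken
lexicographically so output is byte-deterministic.

## Known limitations

- No primer dimer/hairpin thermodynamics beyond the NN duplex Tm, and
  no wet-lab validation metrics (melt peaks, gel purity).
- cDNA only; no intron-containing genomic templates.
- The in-silico PCR mismatch model is positional, not thermodynamic; a
  3′ mismatch is treated as fully refractory.
- Gapped alignments are handled by masking, not by realigning; the
  package never calls an aligner.
- MFI inputs are per-population summaries; there is no FCS parsing or
  gating.
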