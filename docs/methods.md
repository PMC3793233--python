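# Methods

This note records the models, defaults and numerical choices behind
`gepi_screen`, and what the synthetic generators do and do not emulate.

## Isolate table construction

Reads are plain FASTA; the display insert is the substring between a
configurable 5' flank (first occurrence) and 3' flank. The 3' flank is
matched at its *last* downstream occurrence so that an insert ending in a
prefix of the flank is not truncated; the failure modes (either flank
missing, 3' before 5') are reported naming the flank. Translation uses the
standard genetic code; codons containing an uncalled base (N) translate to
`X`, and peptides containing `X` are excluded from the table with a logged
warning — a read-quality problem should not silently distort composition
statistics.

Deduplication is by exact amino-acid string equality: selection acts on the
displayed peptide, and synonymous DNA variants of one peptide are the same
isolate for reporting purposes (DNA-level dedup can be had by tabulating
inserts before translation). Multiplicity counts sequenced colonies; the
first label seen names the merged isolate. Integrity flags are judged on the
frame-0 translation: full-length iff the translated product before any stop
has the expected display length (15 by default), internal stop iff `*`
occurs before that length, frameshift suspected iff the insert length is not
divisible by 3. A truncated but clean isolate (12-mer from a 36-nt insert)
therefore carries all-false flags except full-length.

## Enrichment statistics

A randomization scheme is enumerated by brute force over its codons
(NNN: 64, NNK/NNS: 32 with the single TAG stop). Expected residue
probabilities are conditioned on non-stop codons, because a displayed
peptide cannot contain a stop — under NNK, p(Ser) = 3/31, p(Trp) = 1/31.
The scheme is configurable (default NNK, the standard single-stop
randomization for display libraries; NNS/NNN/custom selectable) and results
should always be reported alongside the scheme used, since the true scheme
of a given library may not be published.

Observed counts are weighted by isolate multiplicity by default: every
sequenced colony is one draw from the selected population. Variable-length
isolates contribute their own residues — no padding — so a 12-mer among
16 15-mers with the dominant clone at multiplicity 49 gives
N = 49·15 + 15·15 + 12 = 972 (unweighted: 252). Both choices are exposed.

The 95% interval on the observed proportion is the exact Clopper–Pearson
interval computed from beta quantiles, with the conventional boundary values
(low = 0 at k = 0, high = 1 at k = N). Significance is "expected outside the
interval": enriched when p_r < low, depleted when p_r > high. Clopper–Pearson
is conservative — coverage is at least nominal for every (p, N) — which the
test suite checks by Monte Carlo. Class rows (default partition: acidic DE,
basic KRH, polar STNQYC, non-polar GAP, hydrophobic VLIMFW; configurable)
sum member counts and expectations and recompute the exact interval on the
class count. No multiple-testing correction is applied by default; a
Bonferroni-style family level is available via `bonferroni_level()`.

## Sequence features

Hydroxyl/sulfoxyl residues are {Ser, Thr, Tyr, Cys}. Met is excluded: its
thioether has no exchangeable proton, and the bundled isolate counts are
only consistent with Met excluded. The set is a parameter (e.g. {S, T, Y}
restricts to hydroxyls proper). Positional span is
(max − min)/(length − 1) over the scored 1-based positions — 1.0 means the
scored residues reach both termini, a singleton spans 0.

Helix propensity is the mean over residues of the Pace–Scholtz ΔΔG scale
(kcal/mol, Ala = 0 reference, Pro 3.16 the strongest breaker), bundled as
`data/pace_scholtz_1998.tsv`; alternative scales can be passed in. Only
orderings should be interpreted — the mean of a free-energy scale is a
ranking device, not a folding prediction.

Doubling times are fitted by linearizing OD(t) = OD₀·2^(t/T_d) to
log₂ OD = log₂ OD₀ + t/T_d and running ordinary least squares; T_d is the
reciprocal slope and its 95% CI is the inverted t-interval on the slope
(unbounded above if the slope interval crosses zero). A non-positive fitted
slope raises a distinct no-growth error rather than returning a nonsense
time. The linearization weights early points more than a direct nonlinear
fit would; for the clean exponential-phase series this is meant for, the
difference is negligible.

## Structural descriptors

Structures are single- or multi-model PDB (one frame per MODEL), parsed with
Biopython and validated: every residue must carry N, CA, C, and all frames
must share atom naming/ordering. Coordinates are Å, residues 1-based,
single-chain only.

Torsions use the standard atan2 formulation, signed by the right-hand
convention about the p2→p3 axis, range (−180°, 180°]; collinear triplets
raise a geometry error. φ = C(i−1)–N–CA–C and ψ = N–CA–C–N(i+1), undefined
at the respective termini.

**Φᵢⱼ.** The improper dihedral over (polarᵢ, CAᵢ, CAⱼ, polarⱼ), where the
polar atom is OG/OG1/OH/SG for Ser/Thr/Tyr/Cys. "Backbone carbons" is taken
as the α-carbons; the atom quadruple is recorded in every
`ImproperDihedralSeries` so the choice stays auditable. The pair is
canonicalized to i < j; the descriptor is symmetric under reversal. The
same-face criterion is |Φᵢⱼ| ≤ 90° (threshold configurable), and
`same_face_fraction` reports the per-frame fraction over an ensemble, using
every frame given.

On an ideal helix, Φᵢⱼ for residues s apart tracks the helical-wheel offset
wrap(s·100°) — but only asymptotically. The torsion is measured about the
CAᵢ–CAⱼ axis, which at small spacings tilts far from the helix axis (67° at
s = 1: chord 3.52 Å vs rise 1.5 Å), distorting the angle by up to ~66° at
s = 2 regardless of side-chain geometry. The test suite therefore validates
Φᵢⱼ against an exact closed-form cylinder-lattice model (CA radius 2.27 Å,
rise 1.56 Å/residue, twist −98.9°/residue, side chains tilted 30° toward the
N-terminus with azimuth trailing the radial direction by 46.2° — all
measured properties of the ideal L-helix, not fitted knobs), which agrees
within 5° at every spacing; the plain wheel offset is accurate to ~20–30°
only for s ≥ 3. The qualitative conclusions are unaffected: spacing-7 pairs
are same-face (Φ ≈ −25°), spacing-2 pairs are opposite-face (|Φ| ≈ 134°).

**Percent helicity.** A residue is helical when φ ∈ [−100°, −30°] and
ψ ∈ [−67°, −7°] and it belongs to a run of ≥ 4 such residues; the per-frame
fraction is over assignable (interior) residues and the report averages
frames ×100. This is a φ/ψ-window surrogate for hydrogen-bond-based
assignment (STRIDE/DSSP): it reproduces the extremes exactly (ideal helix
100%, extended strand 0%) but its absolute values on intermediate ensembles
can differ from those programs, so comparisons should stay within one
assignment method. Windows and minimum run length are parameters.

## Synthetic generators

All generators are deterministic given a seed and emit structures that
round-trip through the PDB writer/parser.

*Libraries.* `generate_naive_library` samples residues with the scheme's
non-stop codon weights — equivalent to codon sampling with stop rejection —
so frequencies converge to the conditioned expectations (checked by
chi-square goodness of fit at n = 50,000). Real libraries hold ~10¹⁰ clones;
desk-scale libraries of 10³–10⁵ reproduce the statistical structure but not
the diversity, so tests about rare-clone dynamics must spike clones in
explicitly.

*Panning.* Each round retains each cell by a Bernoulli draw with its
peptide's retention probability (background for non-binders), records the
survivors, and regrows by multinomial resampling to fixed population size.
Escalating wash stringency is a per-round multiplicative factor on all
retention probabilities. This minimal model yields monotone takeover by the
strongest binder — the qualitative signature of a working screen — but has
no avidity, growth-rate, or surface-saturation effects, and is not fitted to
any experimental enrichment curve.

*Conformers.* Backbones are built from internal coordinates (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/121.7°; ω = 180°) by
natural-extension-of-reference-frame placement, so requested φ/ψ are
reproduced exactly by measurement. Ideal helix: φ = −57°, ψ = −47°; extended
strand: both 180°. Side chains are reduced to CB plus the single polar atom
placed along the CA→CB direction at a residue-appropriate distance (Ser/Thr
2.42 Å, Cys 2.81 Å, Tyr 6.41 Å) with L-chirality (the N–C–CA–CB improper is
+123°); there are no rotamers, so Φᵢⱼ on these fixtures probes backbone
geometry, not side-chain flexibility. Noisy helices perturb every φ/ψ by
i.i.d. Gaussian noise per residue per frame; coils draw φ uniformly from the
sterically plausible region [−180°, −30°] ∪ [30°, 180°] and ψ uniformly from
the full circle — a null model for helicity (<10% assigned) and same-face
statistics (fraction ≈ 0.5), not a thermodynamic coil. Percent helicity is
monotone non-increasing in the noise amplitude (checked at 0/10/30/60°).

What passing these tests shows — and does not. The synthetic ensembles
validate the descriptors' geometry and conventions exactly; they say nothing
about whether a given real peptide holds a helix in solvent. That question
belongs to molecular dynamics with a physical force field, whose
trajectories this package analyzes but does not produce.

## Pipeline and CLI

`run_pipeline` takes one YAML config (every CLI flag has a config twin),
validates inputs before any stage runs, executes isolates → enrichment →
features, and writes TSVs plus a plain-text log with version, parameters and
stage summaries. Data outputs are bit-identical across reruns of the same
config; the log line carrying the wall-clock timestamp is the deliberate
exception. Binding-assay fold changes are ratios of replicate means with
first-order (delta-method) SEM propagation. CLI exit codes: 0 success,
1 input/config error, 2 internal error.

## Known limitations

- Peptide-level dedup conflates synonymous DNA variants (option noted above).
- The helicity surrogate is not STRIDE; absolute percentages differ on
  intermediate ensembles.
- The panning simulator is qualitative; its fold changes should not be read
  against experimental enrichment factors.
- Single chain, no insertion codes, no altlocs in structure handling.
- Chromatogram parsing and base-quality trimming are out of scope; reads are
  taken as called.
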