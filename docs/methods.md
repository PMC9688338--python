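# Methods

This note records the models, defaults and design choices behind `gswnet`,
and what the synthetic validation does and does not establish.

## Sensor preprocessing

Third-order Butterworth stages — high-pass 0.5 Hz, low-pass 50 Hz,
band-stop 47–53 Hz, band-stop 97–103 Hz — are applied as second-order
sections, forward–backward (`sosfiltfilt`). Zero-phase filtering doubles
the effective order but, crucially, does not shift event latencies that
later anchor source localization. The 97–103 Hz stage only exists below
Nyquist for sampling rates above 206 Hz; at lower rates it is skipped with
a warning. Common average referencing follows filtering.

Spike events are defined on the global field power (the spatial standard
deviation of the scalp field per sample, a reference-independent quantity):
every GFP local maximum with prominence ≥ 10 µV marks a spike, and the
event latency is the temporal midpoint, rounded half down, between the peak
and the foot of its ascending limb (the nearest preceding local minimum).
Events closer than a 0.1 s refractory interval collapse to the larger peak.
The 10 µV default suits the synthetic cohort's amplitude regime
(≈ 80 µV discharges over ≈ 3 µV-per-source background) and is the first
knob to adjust for other data. Expert visual artifact rejection is replaced
by a deterministic amplitude criterion (reject epochs with any
|sample| > 300 µV).

Epochs span 2 s before to 2 s after the event; events closer than one epoch
length are treated as one discharge train anchored at its first spike.
Resting-state epochs are drawn uniformly at random (seeded) from windows at
least 2 s away from every detected event, matched in number to the
discharge epochs.

## Source model

The inverse operator is classical sLORETA: minimum-norm kernel
K = Gᵀ(GGᵀ + λC)⁻¹ with the noise covariance C estimated from
resting epochs (diagonal loading 1e-6·trace/N guarantees invertibility
after average referencing), and per-source standardization by the square
root of the resolution-matrix diagonal [KG]ᵢᵢ. This variant has exactly
zero localization error for a noiseless single source, which the tests
verify for every column of a 19×60 random lead field.

Two defaults matter:

* **Regularization** λ = trace(GGᵀ)/(trace(C)·SNR²) with SNR = 3 — a
  fixed-SNR heuristic, configurable.
* **Forward re-referencing.** Because the data are average-referenced, the
  kernel is built from the average-referenced gain matrix (per-source
  sensor mean removed). Building it from the unreferenced gain instead
  introduces ≈ 30% source crosstalk, which sprays phase-lagged coupling
  onto non-coupled source pairs and materially corrupts downstream
  connectivity. This is the single most consequential numerical choice in
  the pipeline.

ROIs are the sources of maximal squared standardized activity at each
event (window ± 0 samples by default); ties break to the lower index with a
warning. Region naming is delegated to a user-supplied label map.

## Connectivity

Complex coherency is estimated from Welch cross-spectra with 1-s Hann
segments at 50% overlap, giving 1 Hz resolution so the 1–12 Hz analysis
frequencies are integer bins. Cross-spectra are pooled across all segments
of all epochs of a state *before* the division (the consistent estimator);
per-epoch coherency averaged afterwards is noisier at these epoch counts.
The imaginary part of coherency is kept signed in the stored tensor; graph
weights use |ImCoh| because path and clustering definitions assume
nonnegative weights.

The estimator's defining property — instantaneous (zero-lag) mixtures of
independent sources produce no imaginary coherence — is tested directly,
as is the converse (a π/2-lagged pair is recovered with |ImCoh| > 0.95
noiseless, > 0.8 at realistic SNR).

## Network-based statistic

Edge-wise paired t statistics on per-subject state differences are
thresholded (T = 1 for the lenient adjacency-building pass, T = 3.5 for the
strict pass isolating the strongest effects); connected components of the
suprathreshold graph are scored and referred to the permutation null of the
maximum component score under within-subject condition flips, with
p = (1 + #{null ≥ observed})/(1 + n_perm).

Two component statistics are provided. **Extent** (edge count) is the
conventional default. **Intensity** (summed suprathreshold t excess) is
the right choice when the expected alternative is a strong, homogeneous
shift across a few edges: under sign flips such edges remain strongly
correlated (they cross the threshold together whenever the flipped-sign
mean is large), which floors extent-based component p-values near
P(Bin(n,½) ≥ k) ≈ 0.1 regardless of effect size, whereas the permuted
intensities stay far below the observed one. The FWER of both statistics
is verified empirically (≤ 0.075 at nominal 0.05 over 200 null
replicates).

The significant adjacency (components with p < α) gates the weighted
modified networks: |ImCoh| on significant edges, zero elsewhere.

## Graph metrics and small-world propensity

Edge lengths are 1/w. L is the mean over nodes of mean shortest distance
to the other n−1 nodes (Dijkstra); disconnected graphs are reduced to the
largest connected component with a warning. C rescales weights by the
maximum, uses geometric-mean triangle intensity t_i = ½Σ(ŵᵢⱼŵᵢₕŵⱼₕ)^⅓ and
node terms 2tᵢ/(kᵢ(kᵢ−1)) with binary degree; nodes of degree < 2
contribute 0. Both are checked to 1e-9 against exhaustive enumeration
oracles on random ≤ 8-node graphs.

SWP nulls preserve node count, edge count and the exact weight multiset:
the lattice null assigns the largest weights to the smallest ring
distances (ties shuffled, seeded); the random null scatters weights over
uniformly random edge slots. Δ_C = (C_latt − C_obs)/(C_latt − C_rand) and
Δ_L = (L_obs − L_rand)/(L_latt − L_rand) are clipped to [0, 1], degenerate
denominators set the Δ to 0 with a warning, and nulls are averaged over
n_null = 10 realizations by default. φ = 1 − √((Δ_C² + Δ_L²)/2);
δ = (4/π)·arctan(Δ_L/Δ_C) − 1 with arctan(∞) = π/2 when Δ_C = 0 and δ = 0
when both Δ's vanish (these conventions make the closed-form anchors
Δ=(0,1) → φ = 1−1/√2, δ = 1 and Δ_L = Δ_C → δ = 0 hold exactly).

The canonical validation ensemble is a weighted Watts–Strogatz
construction: ring lattice (n = 60, k = 6) with weights exp(−(d−1)) in ring
distance d, each edge rewired with probability 0.1 *keeping its weight*, so
shortcuts inherit strong short-range weights and actually shorten weighted
paths. This ensemble scores mean φ ≈ 0.73; its p = 0 and p = 1 limits both
score ≈ 0.29.

## Integrated value of influence

Degree, neighborhood connectivity (mean neighbor degree), ClusterRank
(10^(−cᵢ)·Σ_{j∈Γ(i)}(kⱼ+1)), local H-index (own h-index plus neighbors'),
and collective influence ((kᵢ−1)·Σ over the distance-2 frontier of (kⱼ−1))
are computed on the binarized support; betweenness uses weighted lengths
1/w with unnormalized pair counts. Each measure is range-normalized to
[1, 100] — not [0, 1], so products never vanish; constant vectors map
to 1. Spreading = (NC′+CR′)·(BC′+CI′), hubness = DC′+LH′, and
IVI = hubness·spreading, renormalized to [1, 100]. Influential nodes
strictly exceed mean + 1 SD (sample SD), so vertex-transitive networks
yield empty influential sets. All six measures are verified exactly
against brute-force enumeration on every 4-node graph and random
5–6-node weighted graphs.

In the cohort pipeline, IVI runs on the group-mean GSW network masked by
the *strict* (T = 3.5) NBS pass. At the synthetic cohort's 12 nodes the
lenient T = 1 component covers most of the graph, saturating the binarized
centralities; the strict mask keeps only the strongest state differences,
on which the hub's degree advantage is visible. On atlas-scale networks
(~80 regions) the lenient mask does not saturate and either choice works.

## Statistical protocol

Per frequency, the Shapiro–Wilk test (α = 0.05) on paired differences
gates a two-sided paired t-test vs the Wilcoxon signed-rank test (normal
approximation with continuity correction, zero differences dropped);
Bonferroni adjustment multiplies by the 12 analysis frequencies. The
cross-frequency analysis is a 2×12 within-subject ANOVA (pingouin), with
Mauchly's test on the frequency factor and Greenhouse–Geisser-corrected
p-values for frequency-involving effects when sphericity is rejected;
partial η² is reported. Type-I error of both paths is verified by
simulation to sit in [0.03, 0.07] at nominal 0.05.

## Synthetic cohort: what it emulates, and what it does not

Defaults: 23 subjects, 19 channels (10–20 labels), 256 Hz, five discharges
per subject placed ≥ 12 s apart, each a 4-cycle 3 Hz spike-wave burst
(triangular spike, rise:fall 1:2, occupying a quarter cycle at 80 µV; then
an opposite-polarity half-sine slow wave at 0.35 relative amplitude — the
polarity swing keeps the 3 Hz fundamental dominant). 3 Hz sits inside the
3–4 Hz generalized spike-wave band and keeps the discharge energy in a
single 1 Hz analysis bin. Background activity is 1/f (pink) noise per
source (SD 3) plus low-amplitude 10 Hz alpha, projected through a random
unit-column-norm lead field with 1 µV sensor noise. Ground-truth event
latencies are obtained by applying the ascending-limb-midpoint rule to the
noiseless, filter-chain-processed template, since zero-phase filtering
slightly reshapes the spike.

The coupling ground truth is a star: node 0 carries all six planted
couplings (independent 0.5 Hz-band narrowband processes at 3 Hz, π/2 phase
lag, gain 3, active only in the ±2 s discharge windows), while the
discharge template is emitted by node 7. Two deliberate physics points:

* a node carrying d independent couplings can be at most ≈ 1/√d coherent
  with each partner (power splits across couplings), so hub edges are
  individually weaker than isolated edges — the star keeps the hub's
  degree advantage decisive anyway;
* the discharge template is common to all reconstructions at zero lag, so
  it inflates only the real part of coherency, which the imaginary part
  discards — the generator node therefore does *not* appear as a hub,
  separating the "generator" and "influential" roles by construction.

The generator does **not** emulate ocular/muscle artifacts, realistic head
anatomy or per-subject forward-model variability (one lead field serves
the whole cohort, as with template-anatomy head modeling). Passing the
end-to-end tests therefore demonstrates the pipeline's correctness and
sensitivity under its stated noise model, not robustness to artifacts or
forward-model error.

## Problem sizes in the validation suite

The test suite runs the full cohort analysis on 20 independent 23-subject
cohorts (500 permutations per NBS pass), 200 null replicates for FWER,
1000/500 replicates for the type-I checks, and 20-network SWP ensembles —
sizes chosen so the complete suite executes in a couple of minutes on one
core while leaving the binomial success criteria (≥ 80%, ≥ 90% of seeds)
with comfortable margins.

## Known limitations

* The weight→length map 1/w makes L sensitive to near-zero weights on
  significant edges; the paired protocol absorbs this through its
  rank-based branch, but single-subject L values on sparse masked networks
  can be large.
* ClusterRank uses plain degree for the out-degree term (undirected
  graphs), and collective influence uses the ℓ = 2 frontier by default.
* The EDF writer targets the plain 16-bit EDF profile (one-second records,
  zero-padded tail) — adequate for round-tripping synthetic recordings,
  not a general-purpose EDF+ implementation.
* Wilcoxon p-values use the normal approximation with continuity
  correction, appropriate at the cohort size (n = 23) the pipeline
  targets.
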