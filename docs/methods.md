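# Methods

This note documents the models behind `dmfsynth`: what is simulated, under
which assumptions, with which defaults, and where the design was genuinely
open.

## Sequence model and melting temperatures

Sequences are uppercase top-strand text over `A C G T N`; `N` is allowed
only in deliberately randomized windows (the cloning barcode) and is
treated as self-complementary under reverse complement. Full IUPAC
ambiguity codes, secondary structure and primer-dimer thermodynamics are
out of scope.

Two Tm models are exposed. Design decisions use the nearest-neighbor
duplex model (unified parameter set, monovalent-salt correction) via
Biopython's `MeltingTemp.Tm_NN`; the Wallace 2+4 rule is retained purely
as an independent sanity oracle for short oligos (the suite checks a rank
correlation > 0.8 between the two on random 14-mers). Defaults: 50 mM
monovalent salt and 3.33 × 10⁻⁷ M excess oligo — 0.1 pmol of each primer
in a 0.3 µl droplet, the working reagent regime of the droplet recipes.
No instrument-software Tm formula is published for this class of device;
plan metadata records the annealing convention of each reaction ("Tm of
primers" for extension stages, "Tm − 5" for library reactions) without
asserting a particular underlying model.

Oligo design rules: extension oligos ≤ 120 nt (longer synthetic oligos
prime poorly) and anneal-region Tm ≥ 60 °C, with a 15 nt floor on anneal
length. Coordinates are 0-based half-open on the top strand; reverse-role
oligos are stored 5′→3′ (reverse complement of their top-strand window).

## Inside-out assembly planning

Planning is greedy outward extension. Each stage determines, per end, the
shortest construct-end window reaching 60 °C (floored at 15 nt), then
appends as much new target sequence as the budget allows. The per-stage
extension budget defaults to 160 nt total, split evenly between the two
ends while both flanks remain (all of it to one end afterwards), and never
exceeding the 120 nt oligo cap minus the anneal length. Ties between left
and right are broken toward equal tails. The stage count and oligo count
therefore follow directly from the flank lengths: a 780 nt target with a
centered 140 nt core has 320 nt flanks per side and plans as exactly 4
two-sided stages — 9 building blocks.

Verification is an exact-annealing overlap-extension oracle: an oligo's 3′
suffix must match the construct end with zero mismatches, and the folded
product must equal the target exactly. Mismatch-tolerant annealing is
deliberately not modeled — the quantity of interest is sequence exactness
of the product, and partial hybridization is the off-track failure mode
the staging exists to avoid. The 64× inter-stage dilution and 4-cycle
program are plan metadata consumed by the protocol compiler, not by the
sequence oracle. Polymerase misincorporation is owned by the fidelity
module, not the planner.

## Combinatorial library planning

A library specification lists positions, each with variants, each variant
one or more template fragments (interval on a source template plus
substitution edits restricted to the terminal 25 nt primer spans —
mutations enter via primer tails only). Adjacent fragments must share an
overlap window of at least the minimal anneal length.

The construction DAG is built in three phases: deduplicated building-block
PCRs (no two non-primer nodes share a (kind, sequence) pair); binary
overlap-extension joins chosen greedily, the junction shared by the most
remaining targets first, with a left-most tie-break that yields left-deep
join trees under uniform sharing; and one external-primer amplification
per selected target. The greedy join heuristic is not provably optimal, so
it is pinned by an exhaustive oracle: on specs small enough to enumerate
(≤ 4-fragment chains, ≤ 8 targets) every per-target binary join-tree shape
is tried and the greedy total is required to equal the minimum. Reaction
recipes default to 10 cycles for joins and 30 for amplifications;
building-block PCR cycles are not separately published and use the
30-cycle amplification program.

## Cartridge model and protocol compilation

The virtual cartridge is an electrode grid with 30 reservoir wells
(groups A/C/D/E of 7–8 wells, 2–40 µl, 5% default dead volume within the
published 0–10% range) along one edge, a storage area of parking anchors,
a dilution zone, six collection wells, a waste port and a PCR lane.
Droplets are 300 nl units. The published cartridge's electrode dimensions
are not printed anywhere, so the grid is configuration; the default is
40 × 20, chosen so that the storage area can park ~24 intermediates at a
4-electrode pitch while keeping a routing corridor between any two parked
droplets under the contamination-spacing rule below.

Routing is breadth-first shortest path with a hard spacing contract: a
moving droplet never enters an electrode within one electrode (Chebyshev)
of any stationary droplet, except on the final approach to an intended
merge partner. This is the in-silico counterpart of the observation that
separately routed droplets show no detectable DNA cross-contamination; the
simulator re-checks the contract on every executed path.

Thermal cycling uses fixed-temperature zones (95 / 62 / 72 °C) and moves
droplets between them; temperature is the zone set-point instantly (ramp
physics is hardware-specific and not modeled). The lane is realized as a
ring of four stations — the three temperature zones plus an ambient rest
station. The rest station is what makes multi-droplet rotation sound:
with three droplets and only three stations there is never a free station
to rotate into without two droplets transiting the same zone. All
co-rotating droplets advance one station per rotation period; the period
is the longest phase dwell (5 s denature, 5 s anneal, 15 s/kb extension),
so shorter phases over-dwell — the only schedule that keeps phase-shifted
droplets lock-stepped on shared fixed-temperature hardware. Because a
single droplet uses the same lockstep schedule, running three droplets
costs only the pipeline fill/drain and transit overhead (measured makespan
ratio ≈ 1.17 for 30 cycles), i.e. lane throughput is effectively tripled.
A hot-start activation hold (600 s at 95 °C) is applied at a droplet's
first visit to the denature station when the program requests it.

Serial dilution is six-fold composed from the cartridge's primitive: merge
with one unit of diluent, split into equal halves, trash one half, recycle
the other. A 64× inter-stage dilution is therefore exactly six 2-fold
steps; a one-shot large-volume dilution is rejected because the droplet
unit volume is fixed. Transit time defaults to 0.1 s per electrode and
affects makespans only, never sequence outcomes.

Compilation emits, for every planned reaction, the dispense/merge of its
input droplets, a thermocycle block, and storage parking of intermediates;
shared intermediates are replicated by merging with a buffer droplet and
splitting (copies halve per replication, volumes stay at one unit). Every
op carries the plan-node id it realizes. Protocols end with an elution or
trash for every live droplet, which a linear well-formedness scan proves.

## Droplet chemistry in the simulator

Composition maps DNA species (sequence strings) to molecule counts.
Integer-valued counts are discrete copies and partition on split by a
seeded binomial(n, ½) draw — required for realism at single-molecule
occupancy; float-valued amounts (primers, buffer) are bulk and halve
exactly. An exact-partition mode forces ideal halving of everything, which
is how the dilution ledger's 2^−k law is read off without sampling noise.

No amplification law is published for this device class; the model is
per-cycle synchronous geometric growth: species ≤ 120 nt act as primers,
longer ones as templates. A primer pair with exact 3′-suffix matches on a
template (an in-silico PCR amplicon, tails and edits incorporated) adds
`efficiency × template copies` product copies per cycle, consuming one
molecule of each primer per new product — so yields cap at the loaded
primer amount (0.1 pmol ≈ 6.0 × 10¹⁰ molecules). Template pairs whose
ends share an overlap window fuse at `efficiency × min(copies)` per
cycle, consuming the fragments: the binary-join mechanism. Efficiency
defaults to 0.9/cycle; 10⁹ copies is the detection threshold used for the
"amplified" flag (a proxy for a sequencable band). A PCR cycle fires each
time a droplet completes a denature → anneal → extend station sequence.
Dwell-time sufficiency (extension rate per kb) is respected by the
compiled schedules but not re-checked chemically. Evaporation, adsorption
and surface fouling are not modeled — DNA does not foul the hydrophobic
surface, and the oil filler suppresses evaporation.

Residual template from pre-dilution stages is deliberately left observable
rather than assumed away: stale primers re-amplify the previous product at
their leftover (64×-diluted) concentration while fresh primers convert it
onward, and the eluted composition reports every species, so the
minor-species fraction quantifies how well the dilution regime suppressed
carry-over. In the fixture runs the intended product dominates by roughly
(1 + efficiency)^cycles over the strongest carry-over species.

## Cell-free cloning statistics

Occupancy after limiting dilution is Poisson; the planner picks
k = ⌈log₂(initial/target λ)⌉ 2-fold steps, so the achieved λ lands in
(target/2, target]. Two regimes are supported and neither is asserted as
"the" operating point, since the published description gives both: λ = 1
maximizes the single-founder fraction λe^−λ, and λ = 0.5 (the default
target) trades empty droplets for a higher clonal-given-amplified
fraction. λ is an *effective* concentration — molecules that adhere to
surfaces and never amplify are outside it, and a droplet is "amplified"
iff it received ≥ 1 effective founder.

Barcodes are uniform over 4^len with no composition bias. Clonality
calling takes a read set (or base-fraction matrix) over the barcode window
and calls clonal iff every position's majority-base fraction reaches the
purity threshold, 0.9 by default — an approximation of visual
heterogeneity calling on chromatograms, exposed as a parameter. With
error-free reads a single founder is called clonal always; at 1% per-base
read error and 20 reads the clonal-call rate stays ≥ 0.99.

## Fidelity model

Errors are substitutions only, independent across bases and clones (no
indels, no hotspots). The error rate is errors/bases; the per-10-kb figure
is truncated to one decimal (19/34 821 × 10⁴ = 5.457 → 5.4), matching how
such rates are conventionally printed, and the "1 per N bp" figure is the
integer floor. For the de novo assembly tallies (22 errors in 9710 bp) the
floor is 441, although the conventional rounded figure 1/450 circulates;
the module reports the computed 441. Error-free probability is
p = (1−ε)^L, exactly log-linear in L; clone screening per variant is
geometric with success p, so a screen of n variants averages n/p clones
(22 variants at ε = 19/34 821 and L = 477 → ≈ 28.5).

## Fixtures: what they emulate and what they do not

No sequence accessions accompany the published demonstrations, so the
fixtures are seeded random sequences at ~50% GC shaped to the printed
dimensions: the reporter-like target (780 nt, 140 nt core, 14-N barcode
window centered in the core, 9 building blocks over 4 stages) and the
Azurin-like library (3 positions × 3 variants from 3 templates, middle
position split into sub-fragments a+b, 30 nt junction overlaps shared
across templates, 24 of 27 combinations selected, 4 fragments per target,
12 deduplicated building-block PCRs). Candidate sequences whose anneal or
junction windows cannot reach 60 °C are rejected and redrawn
deterministically, so fixtures are byte-identical per seed. Passing tests
on these fixtures demonstrates the planning, compilation, execution and
statistical machinery on realistically-shaped inputs; it does not
demonstrate anything about the real genes' sequences, about wet-lab yields
or expression phenotypes, or about error processes beyond the substitution
model above.

## Problem sizes and numerical choices

The shipped runs are desk-scale by design: the library simulation executes
~12 000 droplet ops in about a second; statistical checks use 10⁴ smPCR
droplets, 10⁴ clone-screen replicates and 10³ simulated dilution droplets,
with agreement asserted within three standard errors of the corresponding
closed form. Volume conservation is enforced to 10⁻⁹ nl. Determinism is
end-to-end: identical (protocol, seed) pairs produce bitwise-identical
simulation reports, and all randomness descends from the user seed.

Known limitations: no electrowetting physics (voltages, contact angles,
capacitive energy), no thermal gradients or ramp kinetics, no enzymatic
error correction, no chromatogram parsing (clonality operates on read
sets/base-call matrices), and the greedy join planner is only
oracle-verified optimal on small specifications.
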