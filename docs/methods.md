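# Methods

This note documents the models implemented in `kinnet`, their assumptions,
the defaults that matter, and what the synthetic-data conditions do and do
not demonstrate.

## Residue interaction networks

Nodes are amino-acid residues identified by author numbering
(`chain:seq_id`, insertion codes appended); a bound ligand contributes one
additional node. Two residues are connected when their interaction
strength

    I_ij = n_ij / sqrt(N_i * N_j) * 100   [%]

exceeds `I_min` (default 3.0 %). Here n_ij is the number of side-chain
heavy-atom pairs within 4.5 Å (inclusive at the cutoff; glycine
contributes its CA, otherwise it could never form an edge), and N_i is a
residue-type normalization factor: the largest total heavy-atom pair
count (main chain plus side chain, 4.5 Å) observed for that residue type
across the input structures. The geometric-mean normalization follows the
established side-chain interaction-strength scheme; a flag switches to the
plain product for sensitivity analysis. Because published normalization
constants are not part of this package, dataset-derived factors are the
default and a user table always takes precedence. Sequence-adjacent pairs
(|Δseq_id| ≤ 1, same chain) are excluded by default: their contact is
covalent, not an interaction.

Edges carry weights w_ij = −log|C_ij| from the residue cross-correlation
matrix, so strongly coupled residues are close in path length. |C_ij| is
clamped to [1e−6, 1−1e−6] before the logarithm to keep all weights finite
and strictly positive. Without a correlation matrix all weights are 1
(topological variant).

The ligand is modeled as a single node by default: an atom-level edge
scheme would need per-atom weights that have no natural analogue of
w_ij = −log|C_ij|. A ligand–residue edge exists when the (ensemble-mean)
heavy-atom contact count is at least 1, and it carries the median protein
edge weight so that path lengths through the ligand are commensurate with
protein paths.

### Betweenness

All-pairs shortest paths are computed with Floyd–Warshall; co-optimal
path multiplicities g_jk and through-node counts g_jk(i) are accumulated
over "tight" edges, where paths within a relative 1e−9 of the minimum
count as shortest (floating-point weights make exact ties meaningless).
Normalized betweenness divides by (N−1)(N−2)/2 with N the size of the
node's connected component; components smaller than 3 have C_b = 0.
The implementation is verified against exhaustive simple-path enumeration
(exact to 1e−12 on all graphs up to 8 nodes) and against an independent
library implementation on connected graphs.

ΔC_b = C_b(holo) − C_b(apo) quantifies ligand-induced bridging: a ligand
that connects two otherwise weakly coupled lobes creates a shortcut that
routes inter-lobe shortest paths through its contact residues, raising
their centrality and lowering that of the old route.

## Ensemble dynamics

Frames are rigid-body fitted (Kabsch, proper rotations only) to a
reference frame (first frame by default, ensemble mean optional) over CA
or backbone atoms. B-factors are (8π²/3)·MSF averaged over each residue's
selected atoms; mean-square fluctuations below 1e−15 Å² are snapped to
zero (they are rounding residue of the frame mean, not motion).
Cross-correlations use CA atoms by default (the backbone variant is a
flag); a residue whose variance is at floating-point noise level —
absolutely (≤1e−18) or relative to the most mobile residue (≤1e−10×max) —
cannot be normalized and gets C_ij = 0 with a warning.

PCA diagonalizes the Cartesian covariance of the selected atoms.
"Lowest-frequency modes" means the largest-variance principal components
(the standard essential-dynamics convention). The mobility profile is the
RMS displacement of each residue's atoms over the top three modes,
weighted by the mode variances.

ANM modes come from the standard CA Hessian (uniform spring constant
γ = 1.0, cutoff 15 Å — the conventional defaults). A connected 3-D
structure has exactly 6 zero modes; deviations are warned about, and a
disconnected contact graph is an error naming the components. These modes
are also the displacement basis of the synthetic ensemble generator, which
makes PCA-based mode recovery a closed-loop parameter-recovery test.

## Contacts, SASA, RSA

Atom classification uses an 8-class scheme (hydrophilic, hydrophobic,
aromatic, acceptor, donor, neutral, neutral-donor, neutral-acceptor)
shipped as an editable TSV keyed by (residue type, atom name), with
element-keyed fallbacks for HET groups. The table is a reconstruction of
the published LPC classification, not a verbatim copy of an unpublished
one; unknown atoms fall back to `neutral` with a warning. Each contacting
atom pair receives one interaction class (complementary donor/acceptor
pairs count as hydrophilic; otherwise a fixed priority order decides), so
the class tally always partitions the pair count exactly.

SASA is Shrake–Rupley with a deterministic golden-spiral quadrature
(default 960 points, probe 1.4 Å) over Bondi-style van der Waals radii;
coincident atoms are an error because the quadrature is undefined there.
The isolated-atom area is analytic (4π(r+probe)²) and the implementation
is cross-checked against an independent library. RSA divides residue SASA
by a theoretical unfolded-state (Gly-X-Gly) reference area table; values
slightly above 1 are legitimate for highly exposed residues.

## MM-GBSA and alanine scanning

The binding free energy is assembled per frame of a single holo
trajectory:

    dG_bind = <dG_MM> + <dG_solv> − T<dS>

with ΔG_MM the intermolecular van der Waals and Coulomb terms of
(complex − protein − ligand) on identical coordinates. The
internal-energy difference of the isolated species is neglected — the
standard single-trajectory simplification, which also makes the bonded
terms cancel identically. Solvation combines σ·SASA (σ = 0.0072
kcal/(mol·Å²)) with a pairwise generalized-Born term using HCT-style
descreening Born radii (Bondi radii, offset 0.09 Å, scale 0.8). Entropy
(optional) uses Sackur–Tetrode translation (1 atm), classical rigid-rotor
rotation and quantum harmonic-oscillator vibrations over the
positive-frequency modes of the analytic mass-weighted Hessian of the MM
terms, evaluated on minimized average structures; more than six
near-zero/negative eigenvalues mean the structure is not at a minimum and
raise an error.

The molecular-mechanics parameter set is deliberately minimal:
element-keyed Lennard-Jones parameters, per-(residue, atom) partial
charges defaulting to zero, harmonic bonds from a small ideal-length
table with distance-detected connectivity, 1-2/1-3 nonbonded exclusions,
and no cutoff (exact sums at toy scale). The object of interest is the
free-energy combination and its bookkeeping identities — which hold to
1e−9 by construction and are asserted on every run — not force-field
fidelity; absolute kcal/mol values for real inhibitors are out of scope.

Alanine scanning truncates the targeted side chain beyond Cβ on every
wild-type frame (Cγ replaced by a hydrogen at 1.09 Å along the Cβ→Cγ
vector; for the toy single-pseudo-atom side chains the pseudo atom itself
becomes the hydrogen at 1.09 Å from CA), relaxes only that hydrogen by
adaptive steepest descent (≤1000 steps or max gradient < 0.01
kcal/(mol·Å), gas-phase MM objective), and recomputes the four binding
terms. ΔΔG omits the entropy term. Glycine (nothing to truncate) and
proline (backbone-coupled ring) are skipped with a reason; alanine
reports exactly 0. The term-wise breakdown sums to the total by linearity.
ΔΔG is exactly invariant under rigid-body motion in the MM terms; the
only orientation dependence is the finite SASA quadrature (≈0.5 % of the
nonpolar term at 240 points).

## Coevolution

Mutual information between alignment columns uses weighted plug-in
frequencies in nats; sequence pairs with a gap in either column are
dropped from that pair's counts and the marginals are recomputed on the
same subset (which keeps MI non-negative and makes small hand examples
exact); gap-as-21st-symbol is a flag. Sequence redundancy weights are
1/cluster-size under single-linkage clustering at 62 % identity.
Pseudocounts are off by default so closed-form examples are exact; a
Laplace 1/20 option exists for small alignments.

Raw 20-letter plug-in MI is bounded by ln 20 ≈ 3.0 nats, so the
conventional 6.5 significance threshold cannot be a raw-MI value; it is
applied on a permutation z-score scale. The null shuffles each column
independently within its non-gap positions (composition and gap mask
preserved); null moments are pooled over all pairs by default, which
stabilizes the variance estimate at moderate permutation counts
(per-pair moments are a flag). cMI sums a column's MI over partners whose
z exceeds the threshold. pMI maps cMI onto a structure through the
reference sequence (mapping requires ≥ 90 % identity, mismatches are
reported) and averages cMI over residues within 5 Å minimal heavy-atom
distance; residues without neighbors are NaN and reported.

The per-column KL conservation score is the standard probability-weighted
divergence Σ_a P(a)·ln[P(a)/Q(a)] against a background distribution
(database-wide amino-acid frequencies by default, uniform for tests); the
unweighted literal form Σ_a ln[P(a)/Q(a)] is available behind a flag for
comparison. The circular-network export writes per-position ring records
(position, reference residue, KL, cMI, pMI) plus the deduplicated
supra-threshold edge list, the data behind a circular MSA figure.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of an explicit spec plus integer seed.

* **Toy structures** are ideal-geometry backbones (NeRF construction from
  ideal bond lengths/angles and fold-specific torsions) with one pseudo
  side-chain atom (`CB2`) per non-glycine residue, so contact counts are
  small hand-checkable integers.
* **Ensembles** are Gaussian samples along ANM modes: harmonic,
  memoryless, with exactly realizable per-mode variances — a stand-in for
  molecular dynamics that preserves the statistical structure the
  downstream analyses assume (fluctuations, correlations, collective
  modes) but none of MD's anharmonicity, kinetics or solvent effects.
* **MSAs** plant conservation and coevolution over an i.i.d. background.
  Coevolving pairs use a two-state paired alphabet (with probability c
  both columns emit a shared two-state symbol pair) rather than a Potts
  model, because it has closed-form target MI (ln 2 at c = 1) — analytic
  truth beats realism for verification. Real alignments add phylogenetic
  correlation, gaps and composition bias that these tests do not probe.
* **Complexes** place residues on a two-arm layout whose side-chain
  contact network is a single path running down one lobe, across a bottom
  cross-link, and up the other (sequence indices interleaved over the
  arms so spatial neighbors are never sequence-adjacent, and a small
  out-of-plane stagger keeps the elastic network three-dimensional). The
  ligand anchors to each pocket residue at the carbon–carbon LJ minimum
  distance (4.0 Å beyond the side-chain tip), so pocket contacts are both
  network bridges and attractive energetic hot spots; `bridge_strength 0`
  parks the ligand ≥ 20 Å away as a strict non-interacting control.
  The generator verifies its own placement contract (every pocket residue
  within 4.5 Å of a ligand atom, every non-pocket residue beyond) and
  raises if a requested pocket cannot be realized.

Passing tests on these conditions demonstrate the correctness of the
algorithms and their bookkeeping, and the recoverability of planted
signal at the stated sizes (e.g. 2000 sequences, coupling ≥ 0.8, 50
columns) — not the performance of the methods on real kinase data.

## Problem sizes and numerical choices

The shipped demo and verification runs use desk-scale sizes chosen to
make every quantity exactly checkable: 12-residue complexes, 8–25 frame
ensembles, 120–2000 sequence alignments, 25–200 permutations, 240–960
SASA points, entropy on ≤ 50-frame subsamples. All are configuration
parameters; the defaults are the documented study conditions of the test
suite. Tie-breaks and tolerances that matter: shortest-path tie tolerance
1e−9 (relative); correlation clamp 1e−6; static-atom thresholds 1e−15 Å²
(MSF) and 1e−18/1e−10-relative (variance); Hessian zero-mode threshold
1e−8 of the largest eigenvalue; altloc ties resolved to the first
encountered conformer.

## Known limitations

* The energetics backend is a toy force field; only relative/bookkeeping
  statements are meaningful.
* GB radii use a single HCT-style scheme; no salt, no surface-area
  cross-terms in the gradient (minimization objective is gas-phase MM).
* The network ligand node has no atom-level weighting scheme beyond the
  uniform per-atom variant.
* Coevolution z-scores are permutation-based; they reconstruct the
  significance scale conventionally used with the 6.5 threshold rather
  than any specific external tool's corrected score.
* Stockholm/FASTA input assumes uniform-length alignments; no HMM-based
  alignment construction.
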