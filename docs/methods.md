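# Methods

This note records the model, the conventions, and the design choices made
where the design was genuinely open. It states no empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Structure model and filters

A `Complex` is an ordered list of chains of typed residues. Polymer class is
assigned **per residue**: canonical names decide directly (DA/DC/DG/DT →
DNA; A/C/G/U → RNA; the 20 amino-acid names → protein), and modified
residues fall back to atom content — a C1′ sugar marks a nucleic residue,
with O2′ separating RNA from DNA. Modified bases therefore carry the
unknown nucleic token but keep a usable backbone. DNA–RNA hybrid chains
need no special casing because classification is per residue.

A residue **exists** only if every class-required backbone atom is present
with occupancy strictly greater than 0.8. Required sets: protein
{N, CA, C, O}; DNA {P, OP1, OP2, O5′, C5′, C4′, O4′, C3′, O3′, C2′, C1′};
RNA adds O2′. Read literally, this drops 5′-terminal nucleotides that lack
a phosphate; a `permissive_5prime` flag on parsing relaxes the phosphate
requirement for chain-start residues because real termini would otherwise
vanish. Occupancies are rounded to six decimals on parsing so a value
written as 0.8 through float32 file formats still fails the strict
comparison. For alternate locations the highest-occupancy atom per name is
kept; hydrogens, waters and ligands are ignored.

Entry filters: the dataset stage requires ≥ 100 heavy atoms, resolution
≤ 3.5 Å or unreported (NMR-like entries pass), most frequent residue not
UNK occurring > 20 times, at least one nucleic chain with at least one
existing nucleic residue, and total polymer length ≤ 6000. Sequence
coverage ≥ 0.9 is defined as (existing residues)/(reference chain length),
minimum over chains, and is checked only when reference lengths are
supplied — the provenance of a reference sequence is otherwise unknowable
from the coordinate file. The evaluation stage requires 20–1000 residues.

The interface mask flags a protein residue iff one of its side-chain atoms
(any atom outside the required backbone set) lies within 5 Å of a nucleic
side-chain atom among its 48 nearest residues (by representative atom:
Cα/C1′), and symmetrically for nucleic residues. Contacts are symmetric by
construction: a pair found from either side flags both residues.

## Featurization

All residues share one 18-slot backbone frame in the fixed order
N, CA, C, O, CBv, P, OP1, OP2, O5′, C5′, C4′, O4′, C3′, O3′, C2′, O2′, C1′,
Nv. The virtual Cβ uses the standard ideal-geometry construction
CBv = −0.58273431·a + 0.56802827·b − 0.54067466·c + CA with b = CA−N,
c = C−CA, a = b×c. The nucleic virtual atom has no published construction,
so it is defined here as the glycosidic-nitrogen proxy: 1.48 Å from C1′
along the O4′–C1′–C2′ bisector, pointing away from the sugar (toward the
base). 1.48 Å is a typical glycosidic C1′–N bond length.

Edges connect each existing residue to its K = min(32, N−1) nearest
existing residues; distances are rounded to 10⁻⁶ Å before ordering so that
symmetry-induced ties break by lower residue index stably under rigid
motions. Edge features are 16 Gaussian radial-basis bins with centers on
[2, 22] Å and width equal to the bin spacing (20/16 Å), evaluated for all
18×18 slot pairs and zeroed where either slot is absent, concatenated with
a chain-relative positional feature (relative offset clipped to ±32,
one-hot, for same-chain pairs; a separate flag for cross-chain pairs).
Training-time noise adds i.i.d. Gaussian displacements (σ = 0.1 Å) to every
real atom coordinate before virtual atoms or any distance are computed.

`build_graph` emits geometry-level features (polymer-type one-hot, RBF
blocks, masks); the learned node-embedding stack specified for the network
(bias-free linear → layer norm → linear with bias) is applied by the model,
which owns those parameters. This keeps featurization parameter-free and
cacheable across training steps.

## Network

The encoder–decoder follows the standard fixed-backbone inverse-folding
stack: per-edge three-layer GELU message MLPs, mean aggregation over
existing neighbors, residual + layer-norm updates, a position-wise
feed-forward block per layer, and edge-state updates in the encoder.
Defaults: hidden 128, 3+3 layers, dropout 0.1 (toy configurations use
hidden 64 or 32, 2+2 or 1+1 layers, dropout 0). The decoder mixes, per
edge, the (decoded state, edge, token embedding) bundle of visible
neighbors — those fixed, or earlier in the decoding order — with the
(encoder state, edge, zeros) bundle of hidden ones. Fixed residues occupy
order position −1, i.e. before every free position. The output head spans
all 26 tokens; at sampling time the distribution is restricted to the four
canonical bases and renormalized (protein design is deliberately
unsupported — protein context is always fixed). Only nucleic positions are
supervised.

Because no deep-learning framework is part of the package's dependency
footprint, the network runs on an in-package tape-based reverse-mode
autodiff over numpy (`autodiff.py`) with exactly the operations the model
needs; the optimizer is Adam (β₁ = 0.9, β₂ = 0.98, ε = 10⁻⁹) with global
gradient-norm clipping at 1.0.

Specificity inference hides the DNA sequence, decodes 30 times at
temperature 0.6, records the conditional distribution used at each
position's own decode step (not a teacher-forced re-scoring), and averages.
Design uses 10 samples at temperature 0.1 by default.

## Targets, loss, batching

Label smoothing redistributes ε = 0.1 of mass uniformly over the canonical
tokens of the residue's own polymer class (20 amino acids or 4 bases);
unknown tokens receive the plain class-uniform distribution and are never
smoothing recipients, since they are not design targets. The loss is the
printed masked cross-entropy with a **fixed** 1/6000 normalizer, not a
per-token mean. Batches are assembled by weighted sampling with
replacement; a batch closes when the next drawn example would exceed the
6000-token budget, counting all polymer residues of an example. The
specificity augmentations are: uniform targets for protein-free complexes;
protein-chain dropping with probability 0.5 (then uniform targets);
experimental PPM columns where aligned; smoothed one-hots at interface
positions without a motif; uniform elsewhere. The "non-interface" test
reuses the interface mask (5 Å side-chain cutoff, 48-NN restriction).

## PPM alignment

Columns are (A, C, G, T); RNA U is read as T. Normalization adds 10⁻¹⁰ to
every entry of a position and renormalizes. Information content is
IC = Σ_c ln(P_c)/ln(0.25) — note this grows with peakedness (4.0 for a
uniform column, ≈ 49.8 for an ε-normalized one-hot) and is implemented
exactly as defined, as is the ½ factor in the score
½·IC·PCC(column, one-hot). A uniform column has zero variance and its
score is defined as 0. Both orientations are scanned over every offset;
an offset qualifies when its count of overlapping **non-unknown** positions
is ≥ 5 (unknown positions are excluded from both the score and the count).
Ties on alignment scores are detected by exact float equality under
identical summation order — ties in practice arise from symmetric inputs,
and a tolerance would create order dependence. In merging, the "local
score" at a contested position is that position's own IC-weighted PCC;
unknown positions (which have no local score) are resolved by higher
information content; exact ties keep the earlier write, with PPM groups
processed in input order.

## Metrics

PPM MAE is the mean over positions of the summed absolute error over the
four bases (range [0, 2] — the printed sum-over-bases form, not a per-entry
mean); cross-entropy floors predictions at 10⁻¹⁰ before the log. C1′-RMSD
enumerates all contiguous offsets of the shorter chain along the longer,
superposes each overlap with a proper-rotation least-squares fit (an own
SVD implementation; reflections excluded), and returns the minimum. The
dot-bracket crop utility supports multiple bracket families and turns a
pair whose partner is cropped away into a loop.

## Synthetic fixtures

The generator covers every input the pipeline consumes. Nucleotide
templates place the sugar ring as a planar pentagon with substituents at
standard bond lengths (self-consistent to ≈ 0.1 Å, not fiber-diffraction
exact — all tests on these fixtures rely on invariances, not absolute
geometry), plus a single base-proxy side-chain atom (N9) used by interface
tests. Duplexes apply a helical operator (B-DNA: rise 3.38 Å, twist 36°;
A-RNA: 2.81 Å, 32.7°) to strand 1 and a two-fold rotation about x followed
by the same operator to strand 2, which makes a palindromic duplex exactly
rigid-self-symmetric (chain A position i maps onto chain B position i) —
the property behind the strand-symmetry test of specificity prediction.
Protein fragments are ideal α-helices (Cα radius 2.3 Å, 100°/residue,
1.5 Å rise) with a CB proxy placeable at an exact distance from any nucleic
atom; a minimal duplex + single-residue fixture supports bisection of the
interface threshold with no confounding contacts.

The planted dataset displaces each nucleotide's C1′ by one of four
tetrahedral local-frame vectors of magnitude 0.6 Å according to its base,
plus 0.02 Å jitter — the displacement is ≥ 5× any training noise, so the
label is recoverable from geometry by construction (a 1-NN classifier on
intra-residue distances verifies learnability; shuffling labels drops it to
chance). Defaults for the learning-mechanism check: 12 duplexes of 8 bp,
hidden 64, 2+2 layers, batch of 2 examples per step, learning rate 2·10⁻³,
early stopping when greedy training recovery reaches the target. These
sizes are the package's toy-scale defaults; convergence is typically
reached within a few hundred steps.

What the fixtures do **not** emulate: real base atoms and pairing
geometry, sequence-dependent helical irregularity, crystallographic
disorder, and genuine protein side chains. Passing tests therefore
demonstrate mechanism (the pipeline learns geometry→sequence signal and
honors its contracts), not performance on experimental structures.

## Known limitations

- The network is trained only at toy scale here; no released weights are
  loaded, and design/specificity outputs from a freshly initialized model
  only reflect its random parameters.
- Gapped motif alignment, assemblies/symmetry expansion, side-chain
  packing, and pseudo-likelihood scoring are out of scope.
- The 5′-terminal phosphate rule defaults to strict, which removes real
  termini unless the permissive flag is set.
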