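# Methods

## Model and procedure

For an alignment of M sequences and L columns, every ordered column pair
(k, l), k < l, is summarized by the joint distribution p over the 400
ordered amino-acid pairs, estimated from the rows that carry a canonical
residue at both positions. The pair state (r, u) has index 20·(r−1)+u with
residues ordered alphabetically by one-letter code; this indexing is what
the partial-trace sums assume, so it is fixed throughout the package.

The similarity-aware association score is built from the density matrix
ρ_kl = √P A √P (P = diag p, A the 400×400 pair-similarity matrix). Because
A is symmetric positive semi-definite with unit diagonal, ρ_kl is symmetric,
PSD and has unit trace; its von Neumann entropy −Σ λ ln λ and the entropies
of the two 20×20 partial traces give

U_vNE(k,l) = (vNE(ρ_k) + vNE(ρ_l) − vNE(ρ_kl)) / (vNE(ρ_k) + vNE(ρ_l)).

Subadditivity of the von Neumann entropy makes the numerator non-negative,
so U_vNE ∈ [0, 1]. With A = I every density matrix is diagonal and all
terms reduce to the Shannon quantities; the package asserts this identity
to 1e−9. Note that the Shannon baseline statistic U carries a conventional
factor 2 in its numerator that U_vNE does not; the identity-matrix
equivalence therefore holds against the ratio without the factor 2. Both
statistics are reported; all entropies are in nats.

Significance: the null preserves each column's composition but destroys the
pairing. Each of the 25 null draws permutes both columns independently with
a fresh uniform permutation (a stationary draw from the same null as a long
chain of incremental swaps, at a fraction of the cost). The draws are
summarized by a Gumbel model fitted by the method of moments, β = σ√6/π and
μ = x̄ − γβ (γ the Euler–Mascheroni constant; the sample σ uses the n−1
denominator). The observed statistic is converted to a p-value 1 − F(x) and
compared against the Bonferroni-corrected cut-off
c_o = μ − β ln ln(1/(1 − p/N)) with N = L(L+1)/2 — N deliberately counts
the diagonal, matching the cut-off formula's definition, even though only
k < l pairs are tested.

Per-residue aggregation: conn(k) counts the significant pairs containing k;
conz(k) = (conn(k) − mean)/σ is standardized over the positions with
conn > 0 using the population σ (denominator n), which makes the conz
values of that subset exactly mean-0/σ-1. Selection uses conz ≥ threshold
(inclusive), default 2.0.

## The similarity matrix A

A is constructed BLOSUM-style: residue pairs in 3D contact (minimal
heavy-atom distance ≤ 5.0 Å by default, 3.5 Å as an alternative; hydrogens,
waters and hetero groups excluded; intra-chain pairs only) are mapped to
their MSA columns, and for every unordered pair of aligned sequences the
two observed pair states (i, j) increment f(i,j) and f(j,i) symmetrically.
Normalization is a_ij = f(i,j)/√(f(i,i) f(j,j)), diagonal forced to 1.
Where an unobserved diagonal count would make the quotient undefined the
entry is set to 0: an unobserved state carries no similarity evidence, and
pseudocounts would manufacture structure. Finite counts need not give an
exactly PSD matrix, so negative eigenvalues are clipped at 0, the matrix
reconstructed, and the diagonal rescaled to 1 — the resulting perturbation
is bounded by the magnitude of the clipped spectrum.

Structure-to-alignment mapping aligns each chain's one-letter sequence to
the ungapped reference (first) row of the MSA with a global BLOSUM62
alignment; unmapped contacts are skipped with a warning.

For examples and tests the package builds a deterministic full-size
example matrix in code: 20×20 single-residue similarities
s_rt = 2^((b_rt − (b_rr + b_tt)/2)/2) back-transformed from BLOSUM62
log-odds scores, clipped to [0, 1], PSD-repaired, and expanded to pair
states as the Kronecker product S ⊗ S (which preserves unit diagonal and
PSD-ness). This is a synthetic stand-in with the right mathematical
structure, not a corpus-derived matrix; analyses of real families should
build A from contact data (`h2rs build-matrix`) or import a published one.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| p-value target | 1e−4 | family-wise level fed into the Bonferroni cut-off; results are stable across 1e−2…1e−5 |
| shuffles per pair | 25 | null sample for the moment fit; 25 suffices because only two moments are estimated |
| conz threshold | 2.0 | z-score cut for reporting important positions |
| identity bounds | 0.20–0.90 | pairwise-identity window; removes unrelated and near-duplicate sequences before analysis |
| contact cutoff | 5.0 Å | heavy-atom distance defining contacting residue pairs for matrix construction |
| vdW-gap cutoff | 1.0 Å | proximity criterion labelling residues near functional sites as positives in evaluation |

Per-pair random streams are derived from (master seed, k, l), so output is
independent of evaluation order and byte-identical on rerun.

## Synthetic data

The generator draws each background column independently: an alphabet of
1–6 residues chosen at random, frequencies from a symmetric Dirichlet
(concentration 1.0). This range deliberately includes conserved (size-1)
and near-degenerate columns so the degenerate-pair code paths are
exercised; concentration 1.0 spans skewed and balanced compositions.
Planted pairs draw a row's two residues jointly from a pair vocabulary
with probability equal to the coupling strength, otherwise independently
from the vocabulary's marginals; coupling 1.0 is deterministic pairing.
Toy structures are collinear Cα chains with exact inter-residue distances,
so contact lists at any cutoff are known in closed form.

What the generator does not emulate: phylogenetic relatedness between rows
(every row is an independent draw), alignment errors, position-dependent
gap patterns, and the long tail of rare residues seen in deep real
alignments. Passing tests therefore demonstrate the statistical machinery
under a clean independence null and clean planted signals; they do not
quantify robustness to phylogenetic confounding, which the identity filter
only partially mitigates on real data.

## Numerical choices

- Eigensolves use a symmetric solver (`eigvalsh`) only; general solvers are
  never used on density matrices.
- Joint-density eigensolves are restricted to the support of p (states with
  p > 0 contribute zero rows/columns), reducing 400×400 problems to the
  number of observed pair states — an exact reduction, not an
  approximation.
- Eigenvalues in [−1e−8, 0) are clipped to 0 before entropy evaluation;
  anything below −1e−8 raises, signalling an invalid A. U_vNE values in
  [−1e−8, 0) — rounding noise around the subadditivity bound — are clamped
  to 0.
- Degenerate pairs (both columns conserved, or no jointly-canonical row)
  are excluded from testing; a pair whose null has zero spread (e.g. one
  conserved column) is reported non-significant with p = 1 and flagged,
  rather than treated as infinitely significant.
- Probabilities are renormalized over canonical pairs after excluding rows
  with gaps or ambiguity codes at either column, because the 400-state
  formalism is defined over exactly 20×20 residue states.
- Matrix TSVs store values with repr-level precision, so save/load round
  trips are lossless to 1e−12.

## Known limitations

- The moment-fit Gumbel describes the bulk of the shuffle null well, but
  its extreme tail is an extrapolation from two moments; at very small
  Bonferroni fractions the realized family-wise error can deviate from the
  nominal level (observed: a small share of independent-column replicates
  show one spurious cut-off crossing at p = 1e−4).
- Gumbel adequacy is composition-dependent. For columns with rich, balanced
  alphabets the shuffle null approaches normality and a KS test at n = 1000
  resolves the discrepancy; for near-conserved columns the null is discrete
  and a continuous model cannot fit ties. The extreme-value model is best
  suited to the skewed, conserved compositions typical of real alignment
  columns.
- conz is undefined when fewer than two positions have conn > 0 or all
  positive conn values are equal; such runs report significant pairs but an
  empty selection (with a warning) — the z-score carries no information in
  a constant distribution.
- As a local method, transitive correlations are not removed: chained
  pairs are reported as such, which is intended for identifying important
  positions but unsuitable for contact prediction.
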