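# Methods

## The classification problem

Hydrogenases — the metalloenzymes that oxidize or evolve H₂ — fall into three
types by active-site metal content ([NiFe], [FeFe], [Fe]), and within the two
widespread types into groups and terminal subclasses whose members share a
physiological role (respiratory uptake, H₂ sensing, electron bifurcation,
fermentative evolution, …). Predicting function from a catalytic-subunit
sequence therefore reduces to placing the sequence in the right terminal
class of a 38-class taxonomy: 29 [NiFe] subclasses, 8 [FeFe] subtypes, and
the monophyletic [Fe]-hydrogenases. The catalog bundled with the package
(`hydclass/data/class_catalog.tsv`) records each class's name, predicted
function, and provenance flag exactly as curated; the provenance flags are
stored verbatim even though their count (12 newly-flagged rows) sits uneasily
beside the accompanying prose ("11 new subclades") — the catalog does not
arbitrate that discrepancy.

## Classification pipeline

Classification is a three-step process.

**1. Screening gates.** Two checks reject sequences unlikely to be
hydrogenase catalytic subunits: (a) a conserved-domain check — the query must
carry one of the catalytic domains `cl21493` (Complex1_49kDa superfamily,
[NiFe]), `cl14953` (Fe_hyd_lg_C superfamily, [FeFe]) or `pfam03201` (HMD,
[Fe]); and (b) a homology check — the best E-value against the labeled
reference database must be ≤ 10⁻⁵. Either failure yields the final label
NONHYDROGENASE with the failing gate as the reason (the domain gate is
reported first when both fail; the conjunction is order-insensitive). The
domain check needs a profile database that cannot ship with a desk-scale
package, so it is backend-pluggable: an external command template (e.g.
RPS-BLAST against CDD), a mock lookup table (tests and synthetic data), or a
bypass that defers entirely to the homology gate and logs a warning. A
backend-reported domain hit is accepted at E ≤ 0.01 by default (configurable;
no canonical value exists for this cutoff).

**2. k-NN vote.** The distance between two sequences is the E-value of their
optimal Smith–Waterman local alignment — i.e. the distance measure of a
protein homology search. The k references nearest to the query (k = 4 by
default, and only hits passing the homology threshold) vote with their
labels; the majority label wins. Ties are broken in favor of the tied label
owning the nearest neighbor, consistent with the homology-search framing (no
canonical tie rule exists; this is the package's choice). Decoy families —
Nuo, Ehr, NARF, HmdII, homologous to hydrogenases but not H₂-metabolizing —
are first-class labels in the reference set; a decoy majority yields
NONHYDROGENASE (reason `decoy_majority`, family named) rather than a forced
hydrogenase class. If the domain gate matched a type that conflicts with the
voted type, a warning is attached but the vote is not overridden. When fewer
than k hits pass the threshold, the vote runs over what exists (the homology
gate guarantees at least one).

**3. [FeFe] Group A refinement.** Group A [FeFe]-hydrogenases diversified
through domain architecture and quaternary structure, not primary sequence,
so the A1–A4 subtypes are read off the conserved domains of the protein
encoded immediately downstream of the catalytic subunit: NuoF → A3; any of
GltA, GltD, "glutamate synthase small subunit", "putative oxidoreductase"
without NuoF → A2; HycB → A4; none of the vocabulary → A1. Precedence for
co-occurring domains is A3 > A2 > A4 > A1 — NuoF's override of the
glutamate-synthase set is explicit in the rules, the rest of the order is a
documented package choice (the source rules are silent on e.g. HycB + GltA);
conflicts are logged and the full 2⁶ truth table is pinned by tests.
Supplying the downstream protein is the caller's responsibility (a second
FASTA with matching ids); gene calling is out of scope. Refinement applies
whenever the vote lands in Group A (the unrefined "A" label or a subtype) and
downstream data is present, because the downstream rules are the
authoritative subtype assignment for this group.

## Alignment scores and E-values

The default distance backend computes exact Smith–Waterman local alignment
in-process via Biopython's `PairwiseAligner` (BLOSUM62; gap open 11, extend 1
in the BLAST cost convention, i.e. a gap of length L costs 11 + L). Raw
scores are converted with the Karlin–Altschul transform,
bits = (λ·S − ln K)/ln 2 and E = m·n·2^(−bits), using the published gapped
parameters for BLOSUM62/11/1 (λ = 0.267, K = 0.041). Two deliberate
simplifications: the search space is the plain product m·n (no finite-size
length correction), and there is no compositional adjustment — neighbor
*ranking*, not absolute E-value fidelity, is what the classifier consumes,
and the homology threshold is configurable. Consequently absolute E-values
differ from any particular external search tool's; an external backend can be
swapped in behind the same hit schema, with ranked neighbor order as the
cross-backend contract. Ambiguity codes X/B/Z are scored by their BLOSUM62
columns, selenocysteine (U) as cysteine, and a terminal stop `*` is stripped
at parse time. The aligner is checked against an independent brute-force
affine-gap dynamic program in the test suite.

## Cross-validation and model selection

`model_eval` estimates precision by K-fold cross-validation (default K = 5):
records are dealt into folds of near-equal size (differing by at most one),
stratified by class where class size permits so no training fold loses a
class entirely; each fold is classified against a reference built only from
the other folds, with the screening gates applied inside the fold against the
training part (a switch disables the gates for ablation). Precision is the
fraction of held-out records whose predicted label equals the known label
(micro-averaged accuracy — the reading consistent with one scalar per fold);
macro-averaged per-class precision is reported alongside. The k-sweep
evaluates k = 1…10 on a single fold assignment, reusing one set of per-fold
alignments across all k, and reports mean ± 2 SD per k. The tool reports the
sweep and defaults to k = 4 — nearly as precise as k = 1 on separable data
and more robust to mislabeled references — but never auto-selects. Fold
assignment is reproducible from (ids, n_folds, seed) and its digest is
recorded in reports.

## Sequence similarity networks

`ssn` builds the network from an all-vs-all hit table: self pairs dropped,
the two directed hits of a pair collapsed to one undirected edge weighted by
the minimum (most significant) E-value — a symmetric rule stable under
duplicate removal — and edges kept only where log₁₀E ≤ the cutoff. Connected
components are computed with networkx; each component carries its modal label
and purity (fraction of labeled members with the modal label). The cutoff
sweep runs from −5 to −200 in steps of −5 by default; "no major change in
clustering" is quantified as a relative component-count change below 2%
between consecutive grid points (configurable — no published criterion
exists). A query can be classified by the modal label of the component it
joins ("unassigned" if its component holds no labeled reference), which
serves as an independent cross-check on the k-NN vote. Exports: edge-list TSV
and GraphML; layout and visualization are out of scope.

## Synthetic data

The curated 3248-sequence reference set is external supplementary data and is
not bundled; `synthetic` generates the stand-in used by tests and the
acceptance script. Each family grows from an independent uniform-random seed
sequence (length 120 by default — a typical catalytic-domain core scale kept
deliberately small for speed), with members derived by per-site substitution
(default rate 0.25) and geometric-length indels (default rate 0.01). The
standard reference is 5 families × 20 members. Independent seeds put
between-family similarity at chance level, so within-family E-values
(~10⁻³⁰ and below) sit far below the 10⁻⁵ gate while between-family E-values
(~1 and above) sit far above it — the separability regime the classifier
assumes. Mock conserved-domain tables are emitted alongside (catalytic
domain keyed to family type; decoys annotated with an unrelated domain), so
the gates behave like a real profile search on this data.

What the generator does *not* emulate: tree-structured evolution within
families, shared ancestry *between* classes (real [NiFe] subclasses are
homologous to each other and to the decoys, with a continuum of inter-class
E-values), realistic residue composition (flat by default; a background-
frequency option exists), domain-architecture variation, and class
imbalance. Perfect synthetic CV precision therefore demonstrates the
pipeline's correctness in the separable regime, not the ~99.8% figure
attainable on the real curated reference, where inter-class homology makes
the problem genuinely hard at the boundaries.

## Numerical and degenerate-input choices

- Hit ordering is total: ascending E-value, then descending bit score, then
  subject id — so predictions are invariant to reference record order.
- Local-alignment scores are floored at 0; a query with no positive-scoring
  overlap simply fails the homology gate.
- Vote ties: nearest tied label (above). Modal-label ties in SSN components:
  lexicographically smallest subclass code.
- Empty neighbor lists cannot reach the vote (callers must screen); batch
  classification isolates per-record errors into their own output rows.
- E-value of 0 maps to log₁₀E = −∞ and always passes any cutoff.

## Problem sizes

Tests and the acceptance script run on references of 24–100 sequences of
length 60–120 (the standard 5 × 20 reference for CV; 3 × 8 for network
sweeps; 100 random pairs ≤ 40 residues for the aligner oracle; 25 random
databases for the k-NN oracle). These sizes were chosen as the smallest at
which every contract under test is non-trivially exercised.

## Known limitations

- Absolute E-values are backend-specific (plain m·n space, no composition
  adjustment); only rankings and the thresholded gate are contract-stable.
- The domain gate is only as good as its backend; the bypass backend reduces
  screening to homology alone.
- The Group A precedence beyond NuoF's override is a package decision, as is
  the 2% sweep-stability tolerance and the 0.01 domain-hit E-value.
- The classifier offers vote counts, not calibrated probabilities.
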