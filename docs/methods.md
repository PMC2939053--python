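# Methods

## The census model

The pipeline operates entirely in protein space. For each protein it joins
four independent annotation tracks — Pfam domain hits, predicted TM
helices, a predicted signal peptide, and the parent species — into a
`ProteinArchitecture`, then evaluates a set of declarative class rules
against it. A rule is a conjunction of:

* required accession groups — the protein needs ≥1 hit from *each* group
  (a group with several accessions expresses "any of these families", e.g.
  the protein kinase group {PF07714, PF00069});
* forbidden accessions;
* a TM-helix count constraint (`exactly k`, `at least k`, or
  unconstrained), always evaluated on the **corrected** helix list;
* a signal-peptide requirement (required / forbidden / any).

Classes are non-exclusive labels: a protein with one corrected TM helix,
LRR repeats, a TIR domain and a kinase domain is simultaneously a
Toll-like receptor and an LRR-receptor kinase. Whether upstream tables
treat these as disjoint is a presentation choice; counting both and also
exposing their intersection (by composing rules) loses no information.
The containment laws these definitions imply — TLR ⊆ LRR_RECEPTOR ⊆
LRR_PROTEIN, LRR_RK ⊆ LRR_RECEPTOR, SECRETED_LRR ∩ LRR_RECEPTOR = ∅ — are
enforced as a post-census assertion suite (`validate_nesting`) and in the
test suite.

Upstream significance filtering is assumed done by the Pfam scan itself
(family-specific gathering cutoffs). The readers therefore apply no score
threshold; an optional e-value filter exists but is off by default.
Overlapping or duplicate domain hits are all retained — LRR counting is
per hit, not per merged repeat region, which is conservative for the only
place the distinction could matter (classification requires merely ≥1 LRR
hit, where the two conventions agree).

## The signal-peptide / TM correction

HMM-based topology predictors can report an N-terminal signal peptide as a
membrane helix. Any predicted helix sharing at least one residue with the
signal-peptide region (residues 1..sp_end) is removed before counting;
the threshold is configurable (`min_overlap`) but one shared residue is
the default reading of "overlap". The operation is idempotent and
monotone: correcting twice changes nothing, and removing the signal
peptide can only increase the corrected helix count. The
`ProteinArchitecture` type enforces `tm_corrected ⊆ tm_raw` and the
no-overlap property as invariants, so no downstream consumer can see an
uncorrected count by accident. Disabling the correction (for measuring its
effect) treats the signal peptide as absent during assembly, which routes
the raw helix list into classification.

## Gene-model anomaly detection

Manual curation of suspicious receptors is made deterministic with two
parametrised detectors:

* **N-terminal extension.** Given an alignment of the query with ≥1 close
  homologs, the homolog-supported region starts at the first column where
  at least `occupancy` (default 0.5) of the non-query rows are non-gap.
  The overhang is the number of query residues before that column; a
  report is issued when it reaches `min_overhang` (default 100 residues).
  The defaults are deliberately loose: the motivating curated case has a
  560-residue overhang, far above any plausible threshold, and families
  with flush N-termini have overhang 0. If a corrected TM helix lies
  wholly inside the overhang, the suggested action is `drop_tm`.
* **Misplaced N-terminal cap domain.** An LRR N-terminal cap family found
  after `position_fraction` (default 0.25) of the protein length implies
  the true start lies at the cap; the residues before it are treated as a
  suspect 5′ extension, with the same TM logic.

`apply_corrections` removes helices wholly inside flagged overhangs.
Because dropping helices can only move a protein's corrected TM count
away from one if it was one, corrections can only decrease per-species
receptor counts — monotonicity that is asserted in tests. The symmetric
defect (a real helix *removed* from the gene model by an in-frame intron)
is not detectable from protein-space evidence; it is supported as a
manual `ManualTMAddition` record only.

Alignment production is out of scope: the module consumes aligned FASTA
from any aligner, and the synthetic generator emits alignments directly.

## Markov clustering of LRR subsequences

LRR regions evolve fast and align poorly over full-length proteins, so
relatedness is assessed on extracted per-hit subsequences. Edges with
e-value ≤ `e_cutoff` (default 1e-15) are weighted −log10(e), capped at
200 (the cap also maps e = 0; 200 corresponds to e = 1e-200, beyond which
weights carry no useful contrast). MCL then runs on the column-stochastic
matrix with max-incident-weight self-loops:

1. expand: matrix power (default 2);
2. inflate: elementwise power (default 1.5, the standard "coarse"
   setting) followed by column re-normalisation;
3. prune entries below 1e-5 and re-normalise;
4. stop when the maximum absolute entry change is below 1e-6, or after
   100 iterations (with a warning and a `converged=False` flag).

Clusters are connected components of the non-zero pattern of the limit
matrix; components of size 1, and nodes with no cutoff-passing edges,
are singletons (reported as one pool — sequences filtered by the cutoff
are not distinguished from never-matched ones, though callers can
recover the distinction from the input graph). Column sums are checked
every iteration and the worst deviation is reported in the result; the
implementation is deterministic (nodes processed in sorted order) and
permutation-equivariant.

This is standard MCL, not the full OrthoMCL protocol: OrthoMCL
additionally normalises reciprocal best hits across species before
clustering, a step whose parameters are not part of this package's remit.
The two parameters that are honoured everywhere are the e-value cutoff
and the inflation. Correctness is established against an independently
coded dense-matrix MCL oracle on random graphs (≤50 nodes) and a frozen
barbell-graph case, plus planted-partition recovery.

For fully self-contained runs a quadratic all-vs-all scorer
(`pairwise_edges`, Smith–Waterman via Biopython with BLOSUM62 and gapped
Karlin–Altschul constants λ = 0.267, K = 0.041) can produce the edge
list; real datasets should use a proper search tool and feed the ABC
edge-list dialect.

## The synthetic-data generator

The generator emulates what the census *reads*, not what sequences *are*:
per-species mixtures of architecture templates (LRR-only; LRR + 1 TM;
LRR + TM + TIR; LRR + TM + kinase; signal peptide + LRR secreted;
multi-domain fungal adenylate cyclase in the conserved N→C order G-alpha
binding → Ras association → LRR → protein phosphatase 2C → cyclase
catalytic domain; NACHT + WD; HET + NACHT + WD; untracked background),
laid out with random linkers, plus two planted artifacts:

* `SP_TM_OVERLAP` — a helix planted inside residues 1..sp_end of a
  signal-peptide-bearing protein; truth labels are computed *without* it.
* `NTERM_EXTENSION` — a prepended extension (default 560 residues)
  carrying the protein's only TM helix, with an emitted homolog family
  whose members are gapped across the extension columns.

Truth labels are computed by running the classifier on the clean
architecture at generation time, which makes truth/rule-set consistency a
construction invariant rather than a hope. Residues are uniform over the
20 amino acids: the pipeline consumes annotations, so sequence realism
would add nothing except where slicing must work. Consequences for
interpretation: passing recovery tests demonstrates the bookkeeping
(parsing, correction, classification, counting) is exact under the
declared statistical structure; it says nothing about upstream annotation
quality, real Pfam score distributions, or alignment quality on real
homolog families.

Each species draws from `default_rng([seed, crc32(species_id)])`, so
species are independently reproducible and datasets byte-identical per
seed. Benchmark problem sizes used by the validation script — 20 species
× 500 proteins for recovery/correction, 50 + 50 families for anomaly
recovery, 100 random graphs of ≤50 nodes for MCL — are chosen so the
whole validation runs in well under a minute while keeping every planted
count comfortably away from small-sample degeneracy.

## Configuration points that are deployment choices

The Pfam accessions for the HET, WD-repeat, LysM and LRR N-terminal cap
families are configuration, not built-in constants: rule sets that need
them (`STAND`, `LYSM_RK`, the misplaced-cap detector) are only
instantiated when accessions are supplied. The package ships
`DEFAULT_ACCESSORY_ACCESSIONS` (HET = PF06985, WD40 = PF00400,
LysM = PF01476, LRRNT = PF01462 — current Pfam accessions) as a
documented default used by the generator and CLI; users tracking a
specific Pfam release should override them. Similarly the generator's
Ras-association (PF00788) and protein phosphatase 2C (PF00481) choices in
the adenylate-cyclase template are current-Pfam stand-ins for domains
whose identity matters to the template's order, not to any rule.

Thresholds exposed in configuration, with defaults: census summary
`high = 20` / `low = 10` LRR proteins per genome; anomaly
`occupancy = 0.5`, `min_overhang = 100`, `position_fraction = 0.25`;
clustering `e_cutoff = 1e-15`, `inflation = 1.5`, `zero_cap = 200`,
`prune_below = 1e-5`, `converge_tol = 1e-6`.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere; dialect conversion happens
  once at parse time.
* Domain sort order is (start, end, accession); at equal start a domain
  token precedes a TM token in architecture strings.
* Empty inputs are values, not errors: empty FASTA → empty list, empty
  edge list → all singletons, empty census → header-only file.
* Strict mode (default) rejects evidence referencing unknown proteins;
  lenient mode drops it. Silent drops hide proteome/annotation mismatches,
  hence the strict default.
* Column re-normalisation guards zero columns (a column emptied by
  pruning would be left as zeros rather than dividing by zero; with the
  default pruning threshold this cannot occur below ~1e5 nodes, since a
  column of n entries summing to 1 has a maximum ≥ 1/n).
* All tabular outputs are written via temp-file-and-rename, so interrupted
  runs never leave truncated tables.

## Known limitations

* The pipeline never runs HMMER/TMHMM/SignalP; garbage annotations in,
  garbage census out.
* Clan-aware merging of overlapping Pfam hits is not implemented; repeat
  counts are per hit.
* The misplaced-cap detector trusts the cap family's positional
  convention; a genuinely internal cap domain would be a false positive.
* OrthoMCL's cross-species normalisation is not reproduced (see above);
  cluster counts on real data are therefore not comparable to OrthoMCL
  outputs, only cluster structure on a given graph is.
* The self-contained pairwise scorer's e-values are calibrated for rough
  ranking, not search-tool parity.
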