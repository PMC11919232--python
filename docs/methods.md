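# Methods

## Model

One transcript is represented as an ordered list of exons in transcript
orientation (1-based inclusive genomic coordinates), a CDS interval in
spliced-transcript coordinates, and an optional transcript-oriented
sequence. Validation is strict and fail-fast: overlapping exons, a CDS
length not divisible by 3, and CDS bounds outside the spliced transcript
each raise a distinct error naming the offending exon/coordinate.

Variant positions use the HGVS-c convention: a coding (or `-`5'UTR /
`*`3'UTR) anchor plus an optional signed intronic offset. Positive offsets
must anchor on the last base of an exon, negative offsets on the first base
of the following exon; an offset exceeding the intron length is an error,
not a clamp. Genomic→cDNA conversion of intronic positions anchors on the
**closer** exon boundary; at the exact midpoint of an odd-length intron the
donor-side (`+`) anchor wins. All coordinate arithmetic is exact integer
work; there is no floating point anywhere in the mapping layer.

Distance convention: the terminal exonic base and the first intronic base
are both **distance 1** from their junction; distance 0 does not exist.
Exon ordinals count **all** exons in transcript orientation, including
non-coding ones (stated in every report).

## Landmark windows (defaults, all configurable per run)

| landmark | extent | consequence in the cryptic tree |
|---|---|---|
| canonical donor | intronic +1,+2 | reject |
| canonical acceptor | intronic −1,−2 | reject |
| donor region | exonic −3..−1, intronic +1..+6 | cap at conditional |
| acceptor region | intronic −20..−1, exonic +1 | cap at conditional |
| branch-point window | 18–40 nt upstream of the intron 3' end | reject |
| hard distance cut-off | < 5 nt from a splice site | reject |
| recommended cut-off | < 15 nt | cap + proximity caution |
| deep intronic | > 100 nt (strictly) from any junction | ideal case note |

For intronic positions the primary class is the most constraining landmark
(precedence: canonical dinucleotide > donor region > acceptor region >
branch window > deep/proximal intronic); all memberships are additionally
carried as tags. Exonic positions are always primary-class `EXONIC`/`UTR`
with region memberships as tags. Ranged variants are classified by the most
constraining endpoint and flagged `SPANS_JUNCTION` when endpoints fall on
different sides of a junction.

The donor/acceptor **region** overlap caps a cryptic-splice verdict at
`CONDITIONALLY_AMENABLE` instead of rejecting outright. Rationale: a
confirmed cryptic-splice variant a handful of nucleotides inside the
extended acceptor region, with canonical splicing demonstrably intact
(e.g. an acceptor −3 change creating a competing acceptor), is documented
as approachable; the distance cut-offs, not region membership, carry the
hard rejection. Canonical dinucleotides and the branch window remain hard
rejections — an ASO there would mask elements canonical splicing requires.

## Exon-skip simulation

Skipping exon *e* removes its coding contribution. Frame is preserved iff
that length is divisible by 3. For in-frame skips with a non-zero codon
phase at the exon's 5' coding boundary, the junction fuses the upstream
split codon's prefix (`phase` nt) with the downstream split codon's suffix
(`3 − phase` nt); the fused codon is classified as `stop_gained`,
`junction_missense`, or `junction_synonymous` (fused amino acid equals
either original split codon's amino acid). Phase 0, or a skip ending at the
CDS terminus, produces no fused codon. Without a transcript sequence the
junction event is reported as undeterminable (a caution, never a silent
pass). The removed fraction is computed over the full CDS including the
stop codon; the size caution fires strictly above 10 %. The test suite
verifies every junction call against an independent full-CDS re-translation
oracle (Biopython) over thousands of random exons.

## Hotspot analysis (missense path)

An exon is called a pathogenic-missense hotspot when it contains at least
`hotspot_min_count` (default 3) (likely) pathogenic missense records **and**
missense records form at least `hotspot_majority_fraction` (default 0.5) of
all (likely) pathogenic records in the exon. Separately, any record with
functional loss-of-function evidence within ±`hotspot_window_nt` (default
90 nt) of the variant blocks skipping. These three constants are pragmatic
operational defaults, **not** published guideline values (the guideline
prescribes the analysis, not its parameters); they are exposed in the
configuration and flagged `non_default_parameters` in every hotspot report.
Malformed table rows are rejected individually with a logged reason;
benign/VUS rows are valid input that simply does not count.

## Determinism and auditability

Identical inputs produce byte-identical reports: every decision node fired
is appended to an ordered trace (`node_id`, question, answer, consequence),
mandatory gates are always evaluated even after an earlier rejection so the
trace is complete, and the effective configuration is embedded in the trace
and the report. Random fixtures are seeded (`numpy.random.default_rng`);
the bundled demonstration transcript bakes its seed in.

## Fixture generators

* The frozen demonstration bundle: a 10-exon, 900-nt-CDS transcript with
  pinned codons so that eight archetype variants exercise every branch of
  both trees (canonical donor, branch window, deep-intronic cryptic, exonic
  cryptic donor, splice-enhancer disruption, skippable nonsense,
  missense-in-domain, missense-in-hotspot), each with its expected verdict.
* Surrogate transcripts for the four published worked examples: two-exon,
  fully coding models whose single intron is long enough that only the
  anchoring junction constrains classification. Only intronic offsets and
  region classes are asserted against these; real reference sequences are
  deliberately not required or shipped.
* Seeded random transcripts for property tests: always valid (stop-free CDS
  ending in TAA, codon-multiple CDS, both strands), with configurable exon
  count and length ranges.

## Scope and limitations

* Observed splicing effects are **inputs**; no splice-site strength or
  effect prediction is performed.
* ASO sequence/chemistry design, exon-inclusion compound design, gapmer or
  siRNA knockdown strategies, large deletions/CNVs/repeat expansions, and
  UTR-stability approaches are out of scope; affected inputs return
  `OUT_OF_SCOPE` or an explicit flag rather than a guess.
* The exon-skip tree evaluates single-exon skips only; out-of-frame exons
  note the multi-exon alternative but do not design it.
* Amenable verdicts are triage outcomes, not treatment decisions: the
  mandatory follow-ups (functional validation of the truncated protein,
  expert consultation) are attached to every amenable/conditional skip
  verdict by construction.
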