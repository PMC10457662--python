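# Methods

## Model

`blockalign` computes pairwise alignment scores under the generalized
affine-gap (Gotoh) model over a position-specific scoring matrix. The DP
matrix is `(|q|+1) × (|p|+1)` with one padding row/column; the target `p`
runs horizontally and the query `q` vertically. A gap of length `g` in the
target (vertical moves, `I` in the CIGAR) at column `j` costs
`Gext·g + Gopenr[j]`; a gap in the query (horizontal, `D`) spanning columns
`j..j+g−1` costs `Gext·g + Gopenc[j] + Gclosec[j+g−1]`. All penalties are
stored as non-positive integers added to scores; constructors reject
positive values rather than negating them. A plain sequence target plus a
substitution matrix is lifted into this representation (profile row `j` =
matrix row of `p[j]`, constant gap arrays), so sequence-to-sequence and
sequence-to-PSSM alignment share one code path. `Gclose` defaults to 0.

Two D variants appear in the recurrence: `D' = max(diagonal, C+close)` and
`D = max(D', R)`. The vertical-gap open reads `D'` of the cell above.
Opening from `D` instead is provably score-identical whenever open
penalties are non-positive (if `D > D'` then `D` came from `R`, and
`R + Gopen + Gext ≤ R + Gext`, the extension candidate); the bordered
storage relies on this only where noted below.

## Block driver

The driver maintains a square `B×B` block, `Bmin ≤ B ≤ Bmax` (powers of
two), stepping by `S = 8` cells:

* **Shift.** After each step the block moves right if the maximum of the
  `S` topmost right-border `D` values is `≥` the maximum of the `S`
  leftmost bottom-border values, else down (ties go right, per the `≥`).
* **Checkpoint.** Whenever a step's best computed `D` beats the running
  maximum, the block position, its right border (`D`, `C`), bottom border
  (`D`, `R`, `D'`) and the trace length are saved. The initial state is a
  zeroth checkpoint with block size 0 and empty borders, so a grow before
  any improvement recomputes the doubled block from the origin.
* **Grow.** If `Y = ⌊B/S⌋−1` steps pass without improvement and
  `B < Bmax`, the driver restores the checkpoint, pops the trace to it,
  doubles `B`, and recomputes the two L-shaped extension rects
  (`(i+Bprev, j, Bprev, B−Bprev)` below, then `(i, j+Bprev, B−Bprev, B)`
  to the right, seeded by the checkpoint borders). `Bprev` is the
  checkpoint's block size, so repeated grows from the same checkpoint
  (allowed when a grown step still finds no new maximum) stay consistent
  with the stored border lengths — the driver forces the counter to the
  threshold after a fruitless grow step so growth can repeat immediately.
* **Shrink.** If the running maximum sits in the `S/4` rightmost cells of
  the bottom border or `S/4` bottom-most cells of the right border, `B` is
  halved and the block re-centred at `(i+B/2, j+B/2)`; a fresh checkpoint
  is saved.
* **Termination.** When both `i+B > |q|` and `j+B > |p|` the loop ends;
  when only one axis is exhausted the block is force-shifted along the
  other, which guarantees the final corner cell is computed before the
  loop can end. In X-drop mode the loop also ends after two consecutive
  steps scoring more than `X` below the running maximum; this check is
  disabled in global mode, where an early break would leave
  `D[|q|][|p|]` uncomputed. The global score is read from that corner
  cell; X-drop returns the running maximum and its position. `curr_score`
  for a step is the maximum over that step's computed rect(s).
* **max_score initialisation** is 0 in X-drop mode (the empty-alignment
  baseline) but `−∞` in global mode, so checkpoints track the best cell
  even when every score is negative.

## Score computation and storage

Rectangular regions are evaluated one vector at a time: column-major with
vectors along rows for right shifts, row-major for down shifts. The
within-vector gap recurrence (`R` for columns, `C` for rows) is an
affine-gap prefix max-scan, evaluated in chunks of `L` lanes (default 16)
with a carry — bit-identical for every `L` and for both orientations,
which the test suite asserts. In the row-major sweep the horizontal-gap
open candidate uses `max(diagonal, R)` instead of the not-yet-known final
`D` of the left neighbour; by the equal-optima argument above this changes
no value, and the gap-open/extend trace bits are computed afterwards from
the true `D`.

Only two border arrays live between steps: the block's rightmost column
(`D`, `C`) and bottom row (`D`, `R`, `D'`), trimmed to the block extent, so
live score storage is `O(Bmax)` cells plus two checkpoints. `D'` is kept in
the bottom border so that a restored checkpoint recomputes bit-identically
rather than up to the equal-optima argument. Any cell outside the borders
reads as the sentinel `NEG_INF = int64_min/4`, large enough in magnitude to
dominate every reachable score and small enough that a few penalty
additions cannot wrap. Rects are clamped at the matrix edges; `B` itself is
never reduced by clamping.

An optional `clamp16` mode re-bases the stored borders after each step to
the step's maximum and saturates them to the 16-bit range, emulating
narrow-lane arithmetic relative to a 32-bit offset; it is off by default
and observationally identical whenever no clamp occurs.

## Traceback

Each computed cell stores a 4-bit code (one byte per cell; the bit-level
packing of hardware implementations is an encoding optimisation, not
semantics): bit 0 — `D` was taken from `R`; bit 1 — `D'` was taken from
`C+close`; bits 2/3 — `R`/`C` extended rather than opened. Encoding the
`D` and `D'` choices separately (rather than one 3-way direction) keeps
the decoder well-defined after a vertical-gap open, which lands on the
`D'` state of the cell above. Ties prefer diagonal over vertical-gap over
horizontal-gap, and gap opens over extensions; any fixed order preserves
the optimal score, this one is fixed for reproducibility. Codes are
pushed rect by rect and popped in whole rects when a checkpoint is
restored. Decoding walks a four-state machine (D, D', R-run, C-run) from
the alignment end to the origin and emits `M`/`I`/`D` runs; the target
(PSSM) side is the reference. Re-scoring the decoded CIGAR must reproduce
the reported score exactly; this audit runs on every alignment the test
suite produces.

## Synthetic data

The generators emulate summary properties of common evaluation data; they
are pure functions of their seed and return the generating edit script, so
realized identity (matches over all alignment columns, gap columns counted
once) is known exactly.

* **Illumina-like** (`illumina_like`): length 101, substitution rate
  0.005, insertion/deletion rate 0.001 each with lengths 1–2. Realized
  identity ≥ 99%.
* **Nanopore-like** (`nanopore_like`): lengths 500–2000, substitution
  0.04, insertion 0.03, deletion 0.03 (single-base events), plus one long
  indel of 50–400 bp with probability 0.1. Realized mean identity ≈ 0.89
  (within 0.88–0.92). The per-error-type split is an emulation choice; no
  homopolymer structure or quality strings are modelled, so passing error
  rates here say nothing about basecaller-specific error profiles.
* **Protein pairs** (`protein_pair`): uniform-random sequences with
  substitutions drawn `∝ 2^BLOSUM62` toward plausible partners and sparse
  1–2 residue indels, calibrated so realized identity lands near the
  target.
* **PSSMs** (`random_pssm`): one favoured residue per position (+4..+8),
  all others negative (−6..−1), constant gap penalties.

These generators define the study conditions used by the acceptance
checks; notably the long-indel length (50–400) does not scale with read
length, which makes short reads proportionally harder than long ones.

## Evaluation and problem sizes

A pair counts as an error when its global block score is below the full-DP
optimum; the percent error of such a pair is `(true − pred)/true`, and
pairs with non-positive true scores are excluded from the mean with a
warning. Percent-of-length block sizes use `max(|q|, |p|)`, rounded up to
the next power of two and floored at 32 cells.

The shipped checks use 200 mixed DNA/protein pairs (lengths 20–300) for
the exactness regime, 200 Nanopore-like pairs for the long-read error
rate, 1000 Illumina-like pairs for the short-read rate, and single
constructed pairs for the grow ablation — sizes chosen so the whole suite
runs in a couple of minutes on one core while keeping the binomial error
of a ~3% rate near one point.

## Known limitations

* Local alignment is not implemented; modes are global and X-drop.
* The full-DP oracle is quadratic and intended for validation, not
  production use on very long sequences.
* With blocks capped at 1%–10% of the sequence length, indels much longer
  than `Bmax` (here: several hundred bp inside reads under ~2 kbp) are
  sometimes scored suboptimally even with growing — the same regime the
  grow-ablation check probes, and the dominant source of the residual
  long-read error rate.
* PSSM construction from MSAs or search results is out of scope; PSSMs
  are read from the documented TSV dialect or generated synthetically.
* Scores are integers throughout; log-odds/probability-space profiles are
  not supported.
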