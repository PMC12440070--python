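# lodust

Statistical identification of low-complexity (LC) DNA regions — including
centromeric satellite and tandem repeats with moderately long motifs — from
a probabilistic model of k-mer counts, with context windows far longer than
classic DUST-style maskers support.

LC sequence causes spurious homology hits and variant-calling artifacts.
Classic maskers either lack a mathematical definition of complexity or
(like SDUST) become infeasible for large windows and over-call long
strings. `lodust` scores a string x by its k-mer count vector
c = (c_t) under a multinomial null model with frequencies q_t derived from
genome-wide GC content:

```
S(c) = Σ_t log c_t! − T·ℓ(x) − f(ℓ(x))
```

where ℓ(x) = |x| − k + 1 is the k-mer count, T is a per-k-mer threshold in
nats (default 0.6, below log 2) and f(ℓ) is the null expectation of
Σ_t log c_t!, computed by a Poisson approximation so that the centred score
Q = Σ log c_t! − f(ℓ) tends to 0 on random strings of any length.  A
closed interval [i, j] is a **good LC interval** when S > 0 and no proper
prefix or suffix scores higher; the reported mask is the union of good
intervals found on both strands, capped at the window size w (default
5000 bp, k = 7).

The search tests every end position with a backward pass that collects
candidate starts from suffix scores and a forward pass that verifies the
score maximum falls at the end, with window-uniqueness skipping, candidate
pruning, an O(1) full-window continuation for megabase satellite arrays,
and X-drop trimming of internal non-repetitive spacers.  A brute-force
oracle (`lodust.oracle`) enumerates good and perfect intervals directly
from the definitions and backs the test suite; `lodust.synth` generates
the deterministic GC-biased hosts, homopolymers, STRs and diverged tandem
arrays the tests run on.

## Worked example

```sh
$ python - <<'EOF'
import lodust as ld
arr = ld.tandem_array(ld.RepeatSpec(171, 12, 0.02, seed=11))   # alpha-satellite-like
seq = ld.implant(ld.random_dna(8000, 0.41, seed=1), arr, 3000)
seq = ld.implant(seq, "A" * 120, 1000)                          # homopolymer
with open("demo.fa", "w") as fh:
    fh.write(">demo\n" + "\n".join(seq[i:i+60] for i in range(0, len(seq), 60)) + "\n")
EOF
$ lodust demo.fa --score
[lodust] k=7 w=5000 T=0.6 gc=0.4087 xdrop=20.0 rho=0.5 strands=2
[lodust] demo: 10172 bp, 2 block(s), 21.36% masked
demo	1000	1120	360.4690
demo	3119	5172	1569.7922
```

The two BED lines (0-based, half-open; 4th column is the detection score
enabled by `--score`) recover exactly the 120 bp poly-A implanted at
position 1000 and the 2052 bp diverged 171 bp-unit tandem array implanted
at 3120, while the random host stays unmasked.  `--mask` writes
soft-masked FASTA instead of BED, `-f` disables the two-strand union,
`--gc` overrides the GC estimate pooled from the input, and `--oracle`
runs the brute-force enumeration on small inputs.

As a library:

```python
import lodust as ld
model  = ld.gc_to_frequency_model(gc=0.41, k=7)
tables = ld.ScoreTables.build(model, w=5000, T=0.6)
seq    = ld.EncodedSequence.from_string("demo", open_sequence)
for iv in ld.scan_symmetric(seq, tables):
    print(iv.name, *iv.to_bed()[1:], iv.score)
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: (t1) the r-independent part of the analytic
minimum-exact-copy-number expression 3 + (3T − ln 2 − ln 3)/(ln 4 − T) at
the default T = 0.6, and (t2) the maximum of f(ℓ)/ℓ over the default
window (ℓ = 1..4994, k = 7, uniform k-mer frequencies), which bounds the
scaling term by the threshold.  Results are written as JSON to `--out`.

See `docs/methods.md` for the model, the search heuristics and their
limitations.
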