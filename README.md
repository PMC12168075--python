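# rnacleave

Top-down mass spectrometry of RNA: exact monoisotopic masses for
chemically modified oligoribonucleotides, backbone fragment (a/b/c/d/
w/x/y/z) enumeration in negative mode, synthetic CAD spectra with a
known guanosine cleavage-preference ground truth, isotope-cluster peak
assignment with internal recalibration, site-specific cleavage-yield
statistics against a random-cleavage null, and alkaline-hydrolysis
product kinetics.

## The scientific problem

Low-energy collisionally activated dissociation (CAD) of gaseous RNA
(M − *n*H)<sup>*n*−</sup> ions cleaves the phosphodiester backbone into
complementary *c* (2′,3′-cyclic phosphate) and *y* (5′-OH) fragments —
the same product chemistry as base-catalyzed hydrolysis and small
self-cleaving ribozymes. Cleavage is not random: sites immediately 5′ of
guanosine dissociate preferentially, an effect probed by atomic
mutagenesis (deazaguanosines c¹G/c³G/c⁷G, N2-methylated m²G/m²₂G,
inosine). This package provides the computational machinery for such
experiments, for mass spectrometrists working on RNA modification
mapping and on the nucleobase–phosphodiester interactions behind the
cleavage preference.

The central statistic is the overall guanosine cleavage yield

> *Y*<sub>G</sub> = 100 · Σ<sub>k ∈ G-sites</sub> [*y*<sub>c</sub>(k) + *y*<sub>y</sub>(k)]

where *y*<sub>c</sub>(k), *y*<sub>y</sub>(k) are the per-site yields of
c<sub>k</sub> and y<sub>N−k</sub> (base-loss variants pooled into their
parents) relative to all c/y signal, and a *G-site* is a phosphodiester
immediately 5′ of a guanosine. Under random cleavage
*Y*<sub>G</sub> = 100·*n*<sub>G</sub>/(N−1); the excess is summarized by
the effective preference factor
γ̂ = [*Y*/(100−*Y*)]·[(S−*n*<sub>G</sub>)/*n*<sub>G</sub>], the per-site
propensity ratio that reproduces the observed yield.

Twelve reference RNAs (8/18/27 nt, 5′-OH/3′-OH, with and without
site-specific modifications) ship as packaged fixtures
(`rnacleave.TABLE1`, `reference_rna(1)`…`reference_rna(12)`).

## Worked example

```sh
$ rnacleave mass RNA1                 # neutral monoisotopic mass, Da
5764.869

$ rnacleave simulate RNA1 -n 7 --seed 1 -o demo
INFO wrote 4529 peaks to demo/peaks.tsv
$ rnacleave assign demo/peaks.tsv RNA1 -n 7 -o demo/assignments.tsv
INFO assigned 541 species to demo/assignments.tsv
$ rnacleave yields demo/assignments.tsv RNA1 -n 7 -o demo/yields.tsv --map demo/map.txt
INFO overall 5'-of-G yield 61.5% (random 35.3%)
```

The simulated (M − 7H)⁷⁻ spectrum of the unmodified 18-mer used the
default cleavage model (guanosine preference factor γ = 2.75, 35%
precursor survival, 10% base loss) and FT-ICR-style noise. The yield
table and cleavage map show what that model implies: the six sites 5′ of
G carry 61.5% of the c/y signal against a 35.3% random expectation
(slightly above the event-level 60% because short terminal fragments
that draw no charge are invisible):

```
5'-ACCCGCAAGGCCGACGGC-3'  (n = 7, 0.39 charges/nt)
site  1 (   C)   c   0.74%  y   1.30%  #######
site  2 (   C)   c   1.34%  y   2.08%  ############
site  3 (   C)   c   1.54%  y   1.72%  ############
site  4 (   G) G c   4.98%  y   6.07%  #######################################
...
```

The same machinery runs in Python:

```python
import rnacleave as rc

seq = rc.reference_rna(1)
peaks, truth = rc.simulate_cad_spectrum(seq, n=7, seed=1)
ions = rc.enumerate_fragments(seq, "cy", max_charge=7, with_base_loss=True)
assignments = rc.match_fragments(peaks, ions, tol_ppm=3.0)
table = rc.site_specific_yields(rc.aggregate_charge_states(assignments), seq, 7)
print(table.overall_g_yield, table.random_expectation)  # 61.5 35.3
print(rc.effective_preference_factor(table.overall_g_yield, seq))  # ~2.9
```

`rnacleave compare` correlates two runs fragment-by-fragment and reports
the fold change at a site (e.g. the ~10-fold suppression configured for
a c³G substitution), and `rnacleave hydrolysis` simulates an alkaline
hydrolysis time course of products h<sub>i-j</sub> and fits per-site
pseudo-first-order rate constants.

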