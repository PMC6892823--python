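# preyid

Fecal DNA metabarcoding prey identification for predators that cannot be
studied invasively — e.g., an endangered estuarine elasmobranch whose diet
must be read from opportunistically collected feces rather than stomach
contents. From paired amplicon reads of marker genes (mitochondrial 12S/16S
rRNA for species-level fish identification, nuclear 18S rRNA for class-level
screening), `preyid` produces per-sample prey composition profiles and
cross-sample comparisons, with every decision rule explicit and tested.

The workflow, per sample and marker:

1. **merge** mate pairs by maximum-score overlap consensus;
2. **cluster** merged reads into OTUs greedily at identity θ_c = 0.97 and
   drop OTUs with fewer than 5 reads;
3. **search** every centroid against the reference database (identity
   = 1 − edit distance / max length, best strand);
4. **calibrate** the per-base sequencing error *e* from OTUs matching the
   host's known reference, giving the identification threshold
   θ_id = 1 − *e* (≈ 0.98 at a 2% error rate);
5. **identify** each prey OTU by a cascade: unique hit ≥ θ_id → species;
   tied hits → exact-match rescue with ~40 bp species *signature tags*;
   unresolved ties → lowest shared taxon (LCA); species implausible at the
   sampling location per occurrence records → relegated to genus (or higher);
   otherwise unidentified;
6. **profile**: remove host reads, rescale prey counts to exactly 10,000 by
   largest-remainder rounding;
7. **compare** samples by Bray–Curtis similarity
   s = 2·Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ), UPGMA dendrograms (Newick export), and
   12S-vs-16S detection concordance.

A synthetic-data generator (`preyid.simulate`) produces reference databases
with controlled divergence structure (within-genus 5% < within-family 12% <
within-order 20%), host-dominated samples with multinomial composition and
per-base substitution error, and exact truth tables — so the whole pipeline
is testable end to end against known ground truth.

## Worked example

```python
from preyid import (PipelineParams, SimulatedCommunity, derive_tags,
                    run_pipeline, simulate_reference_db, simulate_sample)
from preyid.simulate import HOST_SPECIES

db = simulate_reference_db(n_orders=2, genera_per_order=2, species_per_genus=2, seed=1)
prey = sorted(r.lineage.species for r in db
              if r.marker == "12S" and r.lineage.species != HOST_SPECIES)
community = SimulatedCommunity(
    prey_fractions={prey[0]: 0.5, prey[1]: 0.3, prey[2]: 0.2},
    host_fraction=0.6, n_reads=3000, error_rate=0.01, seed=4)
sample = simulate_sample(community, db, "12S")
tags, _ = derive_tags(db, "12S")
result = run_pipeline(sample.pairs, db, PipelineParams(host_species=HOST_SPECIES),
                      "12S", tags=tags, sample_id="SF1")
```

Running this (`python examples/01_simulate_and_identify.py`) prints:

```
merge rate: 1.000
OTUs: 14 (4 after size filter)
host fraction: 0.582 (truth 0.582)
normalized prey profile (sums to 10,000):
  Genosim1x1 simspec1            5464
  Genosim1x1 simspec2            2624
  Genosim1x2 simspec1            1912
exact recovery: True
```

All 3,000 pairs merged; clustering found 14 OTUs of which 4 survived the
5-read filter (one host, three prey); 58.2% of reads were host, matching the
simulated truth; and the normalized prey profile recovers the simulated
0.5/0.3/0.2 composition (5464/2624/1912 of 10,000) with the detected species
set exactly equal to the truth. The other scripts in `examples/` demonstrate
error calibration (`02`), signature-tag derivation and rescue (`03`), and
community comparison (`04`).

A thin CLI mirrors the library for shell use:

```bash
preyid simulate --seed 3 --out sim/
preyid merge sim/S1_R1.fastq sim/S1_R2.fastq -o merged.fasta
preyid cluster merged.fasta --identity 0.97 --min-size 5
preyid tags --db sim/reference.fasta --tax sim/taxonomy.tsv --marker 12S
preyid run --r1 sim/S1_R1.fastq --r2 sim/S1_R2.fastq \
           --db sim/reference.fasta --tax sim/taxonomy.tsv --host "Pristis synthetica"
```

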