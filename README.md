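# denitrait

Digital categorization of archaeal and bacterial genomes by **denitrification
potential** from KEGG Orthology (KO) presence/absence annotations.

Denitrification is the four-step microbial reduction chain

```
NO3-  --(1)-->  NO2-  --(2)-->  NO  --(3)-->  N2O  --(4)-->  N2
```

catalyzed by twelve enzyme genes in four groups: nitrate reductases
(*narG*, *narH*, *narI*, *napA*, *napB*), nitrite reductases (*nirK*,
*nirS*), nitric oxide reductases (*norB*, *norC*, *norV*, *norW*), and
nitrous oxide reductase (*nosZ*). A genome's enzyme complement is encoded as
a 12-digit binary **Denitrifying Enzymes Pattern** in that fixed gene order.
Trait rules then collapse it to a 4-digit **Denitrification Pattern**: step
*k* is scored `1` iff at least one of its enzyme *complexes* is fully
present —

| step | satisfied by |
|------|--------------|
| 1 nitrate reduction | narG ∧ narH ∧ narI, **or** napA ∧ napB |
| 2 nitrite reduction | nirK **or** nirS |
| 3 nitric oxide reduction | norB ∧ norC, **or** norV ∧ norW |
| 4 nitrous oxide reduction | nosZ |

A partial complex (norB without norC, napB without napA) does not count.
The 4096 possible 12-digit patterns map onto exactly 16 codes, each with a
conventional trait name ("Complete Denitrification" for `1111`, "Nitrous
Oxide Reduction Only" for `0001`, ...). The same machinery runs any
complex-based trait ruleset; a two-step nitrogen-fixation instance
(NifHDK / NifENB) is included.

Around the rule engine the package assembles an ecosystem- and
taxonomy-annotated genome dataset: it reads IMG/M-style per-KO genome list
exports and a metadata table (GTDB-Tk lineage, GOLD 5-level ecosystem),
merges them into a presence matrix, derives patterns, codes, trait names
and a lexical genus, detects replicate strains (one strain name, several
genome sequences), computes grouped summaries and filters, annotates
auxiliary pathways (e.g. *nifH*, *glnA*), and exports CSV/TSV/XLSX with
pattern columns protected as text. A seeded synthetic-cohort generator
emits the same file dialect with a planted trait distribution so the whole
pipeline is testable end to end without downloads.

## Worked example

```python
from denitrait import (
    build_denitrification_ruleset, encode_pattern, apply_trait_rules,
    trait_name, denitrification_catalog,
)

catalog = denitrification_catalog()
rules = build_denitrification_ruleset(catalog)

# a genome annotated with napA, napB, nirS, norB, norC and nosZ
present = {g: True for g in ("napA", "napB", "nirS", "norB", "norC", "nosZ")}
pattern = encode_pattern(present, catalog)
code = apply_trait_rules(pattern, rules)
print(pattern, code, trait_name(code))
```

prints

```
000110111001 1111 Complete Denitrification
```

periplasmic nitrate reductase NapAB covers step 1, cd1-type NirS step 2,
the NorBC complex step 3 and NosZ step 4 — every step is catalyzable, so
the genome is a potential complete denitrifier even though 6 of the 12
genes are absent. Conversely:

```python
print(apply_trait_rules("111001010010", rules))   # 1100
```

here *norB* (digit 8) and *norW* (digit 11) are both present but neither
nitric-oxide-reductase complex is complete, so step 3 scores `0`: nitrate
and nitrite reduction only.

The command line exposes the same operations:

```bash
denitrait classify 111000011101        # -> 1011, Nitrate, Nitric Oxide and
                                       #    Nitrous Oxide Reduction Only
denitrait enumerate                    # 4096 patterns -> 16 codes with preimage sizes
denitrait synth --seed 7 --n 1000 --out cohort/
denitrait build --config config.yaml --out dataset.csv
denitrait summarize --dataset dataset.csv --by "Denitrification Traits"
denitrait scholar nosZ --negate absence --portal
```

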