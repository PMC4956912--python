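# kolrank

Identify **key opinion leaders (KOLs)** — the doctors whose publications
and practice shape peer and patient opinion for a disease area — from
heterogeneous health-care data, with no labeled ranking to train on.

Given a disease category *c* and doctors *D* = {d₁, …, dₙ}, ten ranking
features are extracted per (doctor, category) pair:

| group        | features |
|--------------|----------|
| profile      | working years, academic title (0–3), professional title (0–5), hospital level (1–9, grade III class A highest) |
| expertise    | publication count in *c*, mean patient review level (1–9), propagated expertise-label score |
| social trust | distinct coauthors in *c*, cited publications in *c*, social-recognition score ⌊log₁₀ fans⌋+1 |

Each z-normalized feature *fᵢ* induces a ranked list πᵢ. The package's
core is an **unsupervised consistency-weighted rank aggregation**: with
π̄(d) the average ranking and

σᵢ = (1/n) Σ_d (πᵢ(d) − π̄(d))²,

weights solve min_w Σᵢ wᵢ² σᵢ on the probability simplex, giving
wᵢ ∝ 1/σᵢ — features consistent with the consensus earn large weights.
Doctors are ranked by the linear score F(d, c) = Σᵢ wᵢ fᵢ(d, c).
Expertise-label features come from seed labels diffused over the
coauthorship network (L ← αSL + (1−α)Y with S the symmetrically
normalized adjacency). An evaluation harness scores rankings with
NDCG@K, P@10, R-precision and MAP against planted or judged relevance,
with an unweighted mean-rank (Borda) consensus as baseline.

Because real multi-source medical corpora are proprietary, the package
ships a synthetic-data generator that plants per-category expertise and
emulates the qualitative structure such corpora show: bimodal review
levels (peaks at 8–9 and at 1), heavy-tailed follower counts with a few
"star" doctors, quality-assortative coauthorship communities, and
duplicated doctor records across sources.

## Worked example

```python
from kolrank import SyntheticConfig, generate_corpus, rank_category, top_k

corpus, truth = generate_corpus(SyntheticConfig(rng_seed=7))  # 200 doctors, 5 categories
result = rank_category(corpus, "c00")
for name, w in zip(result.feature_names, result.weights):
    print(f"{name:22s} w={w:.3f}")
print(top_k(result, 5))
```

prints

```
professional_duration  w=0.105
academic_title         w=0.122
professional_title     w=0.101
hospital_level         w=0.087
publication_count      w=0.110
patient_rating         w=0.071
expertise_label        w=0.053
coauthorship           w=0.171
citation               w=0.108
social_recognition     w=0.073
['d00032', 'd00179', 'd00099', 'd00146', 'd00065']
```

The weights order inversely to each feature's rank inconsistency σᵢ
(coauthorship agrees most with the consensus here, so it earns the
largest weight), and the top-5 list overlaps the planted KOL set:
three of five, and 15 of the top 30, are planted experts under the
default noise levels.

The same pipeline is scriptable from the shell:

```bash
kolrank simulate --seed 7 --out data/
kolrank ingest   --in data/ --out clean/
kolrank rank     --in clean/ --category c00 --k 30 --out ranked/
kolrank evaluate --in data/ --out eval/
```

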