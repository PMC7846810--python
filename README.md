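# leadfollow

Inference and network analysis of **leading-following behavior** from
discrete presence recordings of individually tagged animals.

Many social species transfer information about resources by *leading*:
an experienced individual guides naïve conspecifics to a location it has
discovered — e.g. Bechstein's bats leading colony members to newly found
day roosts. Field studies of such systems often record only discrete
presence data: RFID readers at boxes, burrows or feeders log a timestamp
and a tag ID each time an animal passes. `leadfollow` turns such logs
into quantified individual influence, for behavioral ecologists working
with passive tagging data:

1. **Event inference** — an individual is *naïve* at a box at time *t*
   if it was never recorded there before *t*, *experienced* otherwise.
   A leading-following (L/F) event is a joint visit of one experienced
   (leader) and one naïve (follower) individual, their reads at most
   `lf_delay` minutes apart; the leader must additionally be past a
   `turnaround_time` since its own first read there, and reads at an
   occupied roost are discarded from the morning `occupation_deadline`
   onward (swarming at occupied roosts produces joint reads that are not
   leading). Joint arrivals of *k* experienced and *m* naïve animals
   yield *k*×*m* events.
2. **Calibration** — the three parameters are chosen from the data:
   the distributions of L/F time differences across a parameter grid are
   compared pairwise with a bootstrapped Wilcoxon rank-sum test; the
   latest deadline whose distribution is undistorted relative to all
   earlier ones wins, maximizing events without admitting swarming.
3. **Networks** — events aggregate (boxes disregarded) into a directed
   weighted network, link follower → leader, weight = number of events;
   density, weakly and strongly connected components summarize how far
   information permeates the group.
4. **Influence** — three centralities: weighted in-degree
   (direct influence only), eigenvector centrality (indirect influence
   along chains of all lengths), and **second-degree centrality**

   *s(i) = k_in(i) + α · Σ_{j ∈ followers(i)} k_in(j)*,

   the balance motivated by observed chain lengths (chains of ≤ 2 events
   dominate), with α = 0.5 by default. Rankings from the three measures
   are compared by Pearson correlation of the rank vectors.
5. **Chains** — directed paths in the event graph (follower of an
   earlier event leads a later one) counted exactly by dynamic
   programming, giving the chain-length distribution that justifies the
   second-degree truncation.
6. **Synthetic colonies** — an agent-based simulator emulates a season
   of exploration, recruitment, box occupation and morning swarming,
   with full ground truth, so every pipeline stage is testable without
   field data.

## Worked example

`examples/03_centrality_toy_network.py` analyzes a five-node network
with follower → leader links 1→4, 2→4, 3→4, 4→5, 5→1 (unit weights):

```
node  in-degree  eigenvector  second-degree(alpha=0.5)
   1        1.0       1.0000          1.50
   2        0.0       0.0000          0.00
   3        0.0       0.0000          0.00
   4        3.0       1.0000          3.50
   5        1.0       1.0000          2.50
```

In-degree makes individual 4 the clear leader (it led three others) with
1 and 5 tied. Eigenvector centrality attributes zero influence to 2 and
3 — they never led — and therefore equalizes the cycle 1, 4, 5.
Second-degree centrality keeps 4 on top (3 + 0.5 × 1 = 3.5) but now
ranks 5 above 1 (1 + 0.5 × 3 = 2.5): node 5's single follower is itself
highly influential.

The other examples show event inference on a hand-written log
(`01_infer_events.py`), deadline calibration on a simulated season with
swarming — pairs involving the 8 a.m. deadline come out significant,
p ≈ 0.001, and the 5 a.m. deadline is selected (`02_calibrate_parameters.py`) —
and the full pipeline with precision/recall scoring against planted
ground truth (`04_full_pipeline.py`).

## Command line

```bash
leadfollow simulate --config sim.yaml --seed 7 --out-recordings rec.csv \
    --out-truth truth.json --out-boxes boxes.csv
leadfollow infer --recordings rec.csv --boxes boxes.csv \
    --lf-delay 5 --turnaround 3 --deadline 5 --out events.csv
leadfollow calibrate --recordings rec.csv --boxes boxes.csv \
    --n-boot 1000 --seed 1 --out report.json
leadfollow network --events events.csv --out network.csv --summary summary.json
leadfollow centrality --network network.csv --measure second_degree \
    --alpha 0.5 --out scores.csv
leadfollow chains --events events.csv --max-len 16 --out chains.csv
leadfollow report --config pipeline.yaml   # one-shot pipeline
```

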