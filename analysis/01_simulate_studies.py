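#!/usr/bin/env python
"""Simulate the two study-mimicking cohorts.

Generates the beta-agonist-like study (9 high-amplitude planted temporal
templates, 50 probes each, one 7-probe gene, 1000 null probes) and the
growth-hormone-like study (12 low-amplitude transient templates, 40 probes
each, elevated noise, 1000 nulls), each over the 3-arm, 5-day design with
10 animals per arm per day (15 at day 27).  Full data matrices go under
scratch/studies/; a small summary lands in results/.
"""
import argparse
import json
from pathlib import Path

from timeclust import ba_mimic_config, generate_study, gh_mimic_config, write_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--datadir", type=Path, default=Path("scratch/studies"))
    args = ap.parse_args()

    summary = {}
    for name, maker in (("ba_mimic", ba_mimic_config), ("gh_mimic", gh_mimic_config)):
        cfg = maker(seed=args.seed)
        em, design, truth = generate_study(cfg)
        write_study(args.datadir / name, em, design, truth, cfg)
        planted = truth.frame["template_id"] != "null"
        summary[name] = {
            "n_probes": int(em.values.shape[0]),
            "n_samples": int(em.values.shape[1]),
            "n_planted": int(planted.sum()),
            "n_templates": int(truth.frame.loc[planted, "template_id"].nunique()),
            "noise_sd": cfg.noise_sd,
            "amplitude": cfg.assignments[0].template.amplitude,
            "multi_probe_genes": {g: int(n) for g, n in
                                  truth.gene_multiplicity().items() if n > 1},
        }
        print(f"{name}: {summary[name]['n_probes']} probes x "
              f"{summary[name]['n_samples']} samples, "
              f"{summary[name]['n_templates']} planted templates "
              f"(amplitude {summary[name]['amplitude']:g}, "
              f"noise sd {cfg.noise_sd:g}) -> {args.datadir / name}")

    args.outdir.mkdir(parents=True, exist_ok=True)
    out = args.outdir / "simulation_summary.json"
    out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
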