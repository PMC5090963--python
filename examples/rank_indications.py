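"""Score a drug profile with two-tier models and print the ranked report.

Trains disease-level and family-level classifiers on synthetic data, fits
pooled empirical-Bayes distributions from out-of-fold training scores, then
scores one drug's docking profile and prints the hierarchical report.
"""

from cpirank import (
    SyntheticConfig, build_endpoints, build_ranked_report, cross_validate,
    fit_eb_from_predictions, fit_endpoint_model, generate, predict_indications,
)

cfg = SyntheticConfig(n_drugs=200, n_targets=30, n_diseases=10, seed=42)
cpi, labels, truth = generate(cfg)
eps_disease = build_endpoints(labels, level="disease")
eps_family = build_endpoints(labels, level="family")

# out-of-fold scores give the EB normalizer unbiased score distributions
oof, _ = cross_validate(cpi, labels, eps_disease, k=10, repeats=1, seed=42)
eb = fit_eb_from_predictions(oof[0], labels)

models = {
    level: {
        code: fit_endpoint_model(
            cpi.scores, labels.label_vector(cpi.drug_ids, pos), endpoint_code=code
        )
        for code, pos in eps.endpoints.items()
    }
    for level, eps in (("disease", eps_disease), ("family", eps_family))
}

# pick the drug with the most known indications so the report has signal
counts = {d: sum(1 for dd, _ in labels.positives if dd == d) for d in cpi.drug_ids}
drug = max(sorted(counts), key=counts.get)
profile = cpi.row(drug)
dconf, fconf = predict_indications(models["disease"], models["family"], profile, eb=eb)
report = build_ranked_report(dconf, fconf, confidence_floor=0.0)

print(f"ranked indication report for {drug} ({counts[drug]} known indications):")
for fam in report.families[:5]:
    print(f"  rank {fam.rank}: family {fam.code}  confidence {fam.confidence:.2f}")
    for code, conf in fam.members:
        print(f"          {code}  {conf:.2f}")

# Confidences are posterior probabilities that the disease belongs to the
# drug's treatable group, comparable across endpoints within this drug;
# families are ranked by their own family-tier model, not by their members.
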