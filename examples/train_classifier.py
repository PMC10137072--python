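"""Train per-category naive Bayes reviewers and triage the whole corpus.

Generates a corpus whose planted class separability fixes the best
achievable balanced accuracy at 0.72, evaluates each category's
classifier by stratified 5-fold cross-validation, and then classifies
every screened fragment as confirmed or unrelated.
"""

from levelmap import (
    CATEGORIES,
    SyntheticConfig,
    classify_corpus,
    cross_validate,
    deduplicate,
    fit,
    generate_corpus,
    labeled_from_truth,
)


def main() -> None:
    cfg = SyntheticConfig(seed=3, n_per_category=500)
    fragments, truth = generate_corpus(cfg)
    unique = deduplicate(fragments)
    print(f"planted Bayes-optimal balanced accuracy: "
          f"{cfg.bayes_optimal_balanced_accuracy:.2f}")

    models, screened = {}, {}
    for category in CATEGORIES:
        labeled = labeled_from_truth(unique, truth, category)
        report = cross_validate(labeled, folds=5, seed=0, category=category)
        print(f"{category}: 5-fold CV balanced accuracy "
              f"{report.mean_balanced_accuracy:.3f} on {len(labeled)} labels")
        models[category] = fit(
            [(tokens, label) for _, tokens, label in labeled], category=category
        )
        screened[category] = [(fid, tokens) for fid, tokens, _ in labeled]

    print()
    for category, summary in classify_corpus(models, screened).items():
        print(f"{category}: {summary.confirmed_count}/{summary.total} confirmed, "
              f"{summary.unrelated_pct:.1f}% unrelated")
    print("CV scores near 0.72 mean the classifiers extract essentially all")
    print("the signal the corpus contains; 'unrelated' fragments are the")
    print("screening false positives the automated review weeds out.")


if __name__ == "__main__":
    main()
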