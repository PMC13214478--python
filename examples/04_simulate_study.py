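"""Simulate a counterbalanced normative study and analyze it.

Twenty virtual listeners each complete 2 training lists and 22 test
lists; paired participants split a permutation of the 44 lists so every
list collects exactly 10 test scores.  The analysis reports list
equivalence, within-subject variability, and the mixed-model training
effect (here with a known injected drift of -0.02 dB per measurement).
"""

import warnings

import srtkit as sk

corpus = sk.generate_synthetic_corpus(n_per_template=120, seed=3)
retained, _ = sk.apply_filters(corpus)
final, _ = sk.trim_by_offset(retained)
lists = sk.optimize_lists(final, n_lists=44, n_iter=50, seed=3)

listeners = sk.make_listeners(20, seed=3, srt_shift_sd_db=0.5)
plans = sk.make_session_plan(20, n_lists=44, seed=3)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    study = sk.simulate_study(
        final, lists, listeners, plans, seed=3,
        learning_db_per_measurement=-0.02,
    )

eq = sk.list_equivalence(study.results)
per_subject, avg_ws_sd = sk.within_subject_stats(study.results)
fit = sk.training_effect(study.results, include_training=True)

print(f"tracks simulated:         {len(study.results)} "
      f"(20 participants x 24 lists)")
print(f"grand mean SRT:           {eq.grand_mean_db:.2f} dB SNR "
      f"(SD of list means {eq.grand_sd_db:.2f} dB)")
print(f"max list difference:      {eq.max_pairwise_diff_db:.2f} dB")
print(f"avg within-subject SD:    {avg_ws_sd:.2f} dB")
print(f"training effect:          {fit.order_slope_db:+.4f} dB/measurement "
      f"(95% CI {fit.order_slope_ci[0]:+.3f} ... {fit.order_slope_ci[1]:+.3f})")
print(f"order F-test:             F(1,{fit.df_den}) = {fit.f_stat:.1f}, "
      f"p = {fit.p_value:.2g}")
print()
print("The grand mean sits near the corpus reference midpoint and small")
print("list deviations indicate equivalent lists.  The order coefficient")
print("picks up the injected practice effect; a single study estimates it")
print("noisily, and averaging replicate studies recovers -0.02 closely.")
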