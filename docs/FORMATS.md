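# File formats

All interchange files are tab-separated text (TSV) or JSON. Frames are
**0-based** everywhere.

## Cohort input directory

```
cohort.tsv            subject, group            group in {AE, UAA}
tasks_pre.tsv         subject + 7 task columns  battery order:
tasks_post.tsv                                  spatial_wm_rt, two_back_rt,
                                                task_switch_cost, trails_b_time,
                                                flanker_incongruent_rt,
                                                digit_symbol_count, meps_steps
ts/<subject>_<session>.tsv      frames x nodes, header row of node ids
motion/<subject>_<session>.tsv  frames x 6: trans_x_mm, trans_y_mm, trans_z_mm,
                                rot_x_rad, rot_y_rad, rot_z_rad
ground_truth.json     planted module assignment, spike frames, effect sizes
                      (written by the simulator only)
```

`<session>` is `pre` or `post`. Task scores are on the raw scale
(reaction-time-like units); missing cells are empty.

## Pipeline output directory

```
mask/<subject>_<session>.tsv     frame, kept, flagged_fd, flagged_dvars (0/1)
conn/<subject>_<session>.tsv     square connectivity matrix, node-id header
                                 row and index column
q/<subject>_<session>.tsv        gamma, run, q  (one row per stochastic run)
q_median/<subject>_<session>.tsv gamma, median_q (full float precision, so
                                 cached reloads reproduce fits exactly)
glmm_fit.json                    coefficients (estimate/se/z/p), sigma_b,
                                 sigma_e, loglik, convergence
plsda.json                       weights, loadings, VIP per task, selected
                                 tasks, explained X/Y variance, error rates,
                                 complete-case count
logistic.json                    one block per discriminant task:
                                 coef/se/p for intercept, q, task, q_x_task
table2_replica.tsv               per task x time: group n/mean/SD and the
                                 two-sample t (pooled and Welch) with p
report.json                      all blocks above + provenance (config hash,
                                 seed, package version) + stage warnings
provenance.json                  config hash used for stage caching
```
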