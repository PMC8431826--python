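# Mixed-effects model families for log response times.
#
# Every family is fit with maximum likelihood, a random intercept per subject
# and (by default) a random slope for trial order per subject. Treatment
# coding references: sham, pre, verb_generation, low. Derived numeric columns:
#   stimulation   1 = active group
#   session_post  1 = post-stimulation session
#   task_sc       1 = sentence completion
#   entropy_high / association_high   1 = above per-task median
#   entropy_c / association_c         per-task mean-centered continuous values
#   boundary / modal                  per-subject controllability covariates
#
# "filter" rows subset the trial table before fitting; "needs" lists derived
# covariates the family requires.

intercept_only:
  fixed: "1"
  filter: {}
  needs: []

both_tasks_boundary_tms:
  fixed: "stimulation * session_post * boundary"
  filter: {}
  needs: [boundary]

task_by_selection_pre:
  fixed: "task_sc * entropy_high"
  filter: {session: pre}
  needs: [entropy_split]

task_by_retrieval_pre:
  fixed: "task_sc * association_high"
  filter: {session: pre}
  needs: [association_split]

boundary_by_entropy_SC:
  fixed: "boundary * entropy_c"
  filter: {session: pre, task: sentence_completion}
  needs: [boundary, entropy_split]

modal_by_entropy_SC:
  fixed: "modal * entropy_c"
  filter: {session: pre, task: sentence_completion}
  needs: [modal, entropy_split]

boundary_by_association_VG:
  fixed: "boundary * association_c"
  filter: {session: pre, task: verb_generation}
  needs: [boundary, association_split]

modal_by_association_VG:
  fixed: "modal * association_c"
  filter: {session: pre, task: verb_generation}
  needs: [modal, association_split]

sham_session_SC:
  fixed: "session_post"
  filter: {group: sham, task: sentence_completion}
  needs: []

sham_session_VG:
  fixed: "session_post"
  filter: {group: sham, task: verb_generation}
  needs: []

tms_session_SC:
  fixed: "stimulation * session_post"
  filter: {task: sentence_completion}
  needs: []

tms_session_VG:
  fixed: "stimulation * session_post"
  filter: {task: verb_generation}
  needs: []

tms_session_boundary_SC:
  fixed: "stimulation * session_post * boundary"
  filter: {task: sentence_completion}
  needs: [boundary]

tms_session_boundary_VG:
  fixed: "stimulation * session_post * boundary"
  filter: {task: verb_generation}
  needs: [boundary]

trialwise_pre:
  fixed: "trial_order * entropy_high"
  filter: {session: pre, task: sentence_completion}
  needs: [entropy_split]

trialwise_post:
  fixed: "trial_order * entropy_high"
  filter: {session: post, task: sentence_completion}
  needs: [entropy_split]
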