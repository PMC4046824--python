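"""Apply the published decision rules to the packaged validation table.

Twenty experimentally validated mouse PDZ-peptide interactions are scored
by two methods; a binder is called at SVM decision score > 0 or at a
normalised PSSM-baseline ratio > 1. Every row is a true interaction, so
the fraction called is each method's true positive rate.
"""

from pdzfam.benchmark import load_validation_table, mdsm_binder, svm_binder, validation_summary

table = load_validation_table()
summary = validation_summary(table)
print(f"{summary.total} validated interactions")
print(f"SVM rule (score > 0):   {summary.svm_tp} binders called, TPR {summary.svm_tpr:.2f}")
print(f"PSSM ratio rule (> 1):  {summary.mdsm_tp} binders called, TPR {summary.mdsm_tpr:.2f}")
print()
for rec in table[:4]:
    print(f"  {rec.domain:14s} {rec.peptide}  svm {rec.svm_score:+.2f} "
          f"({'hit' if svm_binder(rec) else 'miss'})  ratio {rec.mdsm_score:+.2f} "
          f"({'hit' if mdsm_binder(rec) else 'miss'})")
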