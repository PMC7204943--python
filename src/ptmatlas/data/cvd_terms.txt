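# Starter cardiovascular disease term list (one term per line).
# Exact names match case-insensitively after whitespace normalisation;
# a leading '~' makes the term a substring pattern instead.
# This list is an input to the classifier, configurable per analysis.
myocardial infarction
heart failure
congestive heart failure
coronary artery disease
coronary heart disease
atherosclerosis
cardiomyopathy
dilated cardiomyopathy
hypertrophic cardiomyopathy
cardiac hypertrophy
cardiac arrhythmia
atrial fibrillation
ventricular tachycardia
long qt syndrome
hypertension
pulmonary hypertension
stroke
ischemic stroke
aortic aneurysm
myocarditis
endocarditis
pericarditis
angina pectoris
peripheral artery disease
mitral valve prolapse
aortic valve stenosis
congenital heart defect
~cardiac
~cardio
~myocardial
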