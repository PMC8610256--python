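# Synthetic stand-in comorbidity map: predictor name -> ICD-10 code prefixes
# (uppercase, dot-stripped; a diagnosis matches if it starts with a prefix).
#
# The validation study categorised comorbidities "according to the supplement
# information of the original publication", which is not redistributable;
# these are standard ICD-10 ranges (Charlson-style) for the same conditions.
anaemia: [D50, D51, D52, D53, D55, D56, D57, D58, D59, D60, D61, D62, D63, D64]
hypertension: [I10, I11, I12, I13, I15]
heart_failure: [I50]
acute_mi: [I21, I22]
chronic_ihd: [I25]
diabetes_organ: [E102, E103, E104, E105, E106, E107, E112, E113, E114, E115,
                 E116, E117, E132, E133, E134, E135, E136, E137, E142, E143,
                 E144, E145, E146, E147]
cancer: [C0, C1, C2, C30, C31, C32, C33, C34, C37, C38, C39, C40, C41, C43,
         C45, C46, C47, C48, C49, C50, C51, C52, C53, C54, C55, C56, C57,
         C58, C6, C70, C71, C72, C73, C74, C75, C76, C81, C82, C83, C84,
         C85, C88, C90, C91, C92, C93, C94, C95, C96, C97]
metastatic_ca: [C77, C78, C79, C80]
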