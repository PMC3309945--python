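"""Reference datasets.

``INCREASE_COUNTS_2011`` is the published per-term hit-count table from
the April 2011 PubMed snapshot evaluation of the UMLS-synonym expansion:
for each of the 43 query terms, the number of citations retrieved only
by the synonym-expanded query (q5) and the number of non-indexed
citations retrieved by the entry-term query (q3).  It is the canonical
input for :func:`pubmed_expand.reporting.increase_report`.
"""

from __future__ import annotations

INCREASE_COUNTS_2011: tuple[tuple[str, int, int], ...] = (
    ("Neoplasms", 46, 1871),
    ("Hypertension", 23, 10547),
    ("Myocardial infarction", 155, 5298),
    ("Coronary disease", 41, 5397),
    ("Asthma", 133, 4149),
    ("Obesity", 379, 7552),
    ("Liver neoplasms", 641, 266),
    ("Diabetes Mellitus", 9876, 5033),
    ("Inflammation", 361, 13019),
    ("Heart Failure", 272, 6042),
    ("Kidney Failure, Chronic", 81, 372),
    ("Alcoholism", 295, 713),
    ("Epilepsy", 2470, 3256),
    ("Tuberculosis", 1238, 6752),
    ("Liver cirrhosis", 155, 1983),
    ("Kidney Diseases", 2667, 1095),
    ("Cross Infection", 167, 1255),
    ("Parkinson Disease", 411, 396),
    ("Lymphoma", 144, 3939),
    ("Hypersensitivity", 159, 1357),
    ("Breast neoplasms", 0, 11),
    ("Lung neoplasms", 0, 23),
    ("Skin neoplasms", 0, 10),
    ("Melanoma", 0, 2491),
    ("HIV infections", 0, 142),
    ("Brain Neoplasms", 0, 10),
    ("Prostatic Neoplasms", 0, 0),
    ("Arthritis, Rheumatoid", 0, 0),
    ("Neoplasm Metastasis", 0, 0),
    ("Occupational Diseases", 0, 136),
    ("Neoplasm Recurrence, Local", 0, 0),
    ("Substance-Related Disorders", 0, 25),
    ("Pregnancy Complications", 0, 84),
    ("Tuberculosis, Pulmonary", 0, 0),
    ("Genetic Predisposition to Disease", 0, 0),
    ("Wounds and Injuries", 0, 8),
    ("Diabetes Mellitus, Type 1", 0, 1),
    ("Ovarian Neoplasms", 0, 24),
    ("Uterine Cervical Neoplasms", 0, 1),
    ("Arrhythmias, Cardiac", 0, 0),
    ("Pancreatic Neoplasms", 0, 30),
    ("Colorectal Neoplasms", 0, 14),
    ("Lupus Erythematosus, Systemic", 0, 0),
)

#: Row percentages as published alongside the counts (one decimal, "-"
#: where q3 is zero).
INCREASE_PERCENT_2011: dict[str, str] = {
    "Neoplasms": "2.5%",
    "Hypertension": "0.2%",
    "Myocardial infarction": "2.9%",
    "Coronary disease": "0.8%",
    "Asthma": "3.2%",
    "Obesity": "5.0%",
    "Liver neoplasms": "241.0%",
    "Diabetes Mellitus": "196.2%",
    "Inflammation": "2.8%",
    "Heart Failure": "4.5%",
    "Kidney Failure, Chronic": "21.8%",
    "Alcoholism": "41.4%",
    "Epilepsy": "75.9%",
    "Tuberculosis": "18.3%",
    "Liver cirrhosis": "7.8%",
    "Kidney Diseases": "243.6%",
    "Cross Infection": "13.3%",
    "Parkinson Disease": "103.8%",
    "Lymphoma": "3.7%",
    "Hypersensitivity": "11.7%",
    "Breast neoplasms": "0.0%",
    "Lung neoplasms": "0.0%",
    "Skin neoplasms": "0.0%",
    "Melanoma": "0.0%",
    "HIV infections": "0.0%",
    "Brain Neoplasms": "0.0%",
    "Prostatic Neoplasms": "-",
    "Arthritis, Rheumatoid": "-",
    "Neoplasm Metastasis": "-",
    "Occupational Diseases": "0.0%",
    "Neoplasm Recurrence, Local": "-",
    "Substance-Related Disorders": "0.0%",
    "Pregnancy Complications": "0.0%",
    "Tuberculosis, Pulmonary": "-",
    "Genetic Predisposition to Disease": "-",
    "Wounds and Injuries": "0.0%",
    "Diabetes Mellitus, Type 1": "0.0%",
    "Ovarian Neoplasms": "0.0%",
    "Uterine Cervical Neoplasms": "0.0%",
    "Arrhythmias, Cardiac": "-",
    "Pancreatic Neoplasms": "0.0%",
    "Colorectal Neoplasms": "0.0%",
    "Lupus Erythematosus, Systemic": "-",
}

#: Column totals as published with the table.  Note: the published q3
#: total (83341) exceeds the sum of the published q3 rows by 39; the
#: per-row data are taken as authoritative here.
PUBLISHED_TOTALS_2011 = {"q5": 19714, "q3": 83341, "pooled_increase": 23.7}
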