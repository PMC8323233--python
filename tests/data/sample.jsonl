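{"doc_id": "doc-a", "split_role": "train", "sentence_index": 0, "text": "左肺结节", "spans": [["Mass", 2, 4]]}
{"doc_id": "doc-b", "split_role": "unlabeled", "sentence_index": 0, "text": "心包积液", "spans": [["Effusion", 2, 4]]}
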