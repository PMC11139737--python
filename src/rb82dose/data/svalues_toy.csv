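phantom,source,target,s_mGy_per_MBq_h
toy,liver,liver,3.0
toy,liver,spleen,0.5
toy,spleen,spleen,4.0
toy,spleen,liver,0.5
toy,total_body,liver,0.1
toy,total_body,spleen,0.1
toy,total_body,total_body,0.2
toy,liver,total_body,0.05
toy,spleen,total_body,0.05
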