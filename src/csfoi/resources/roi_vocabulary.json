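{
  "schema_version": "1",
  "description": "ROI vocabularies for the intracranial CSF-space analysis: 45 regions measured on IVIM perfusion-fraction maps and 7 regions measured on cardiac-gated 4D-flow MRI, plus the name mapping used to attach measured velocity amplitudes to IVIM regions. The lower cerebral aqueduct on 4D flow is treated as equivalent to the upper part of the fourth ventricle on IVIM.",
  "ivim_rois": [
    "foramen_magnum",
    "rt_foramen_of_luschka",
    "lt_foramen_of_luschka",
    "foramen_of_magendie",
    "lower_4th_ventricle",
    "upper_4th_ventricle",
    "lower_cerebral_aqueduct",
    "upper_cerebral_aqueduct",
    "anterior_3rd_ventricle",
    "posterior_3rd_ventricle",
    "rt_foramen_of_monro",
    "lt_foramen_of_monro",
    "rt_anterior_horn",
    "lt_anterior_horn",
    "rt_lateral_ventricle_body",
    "lt_lateral_ventricle_body",
    "rt_trigone",
    "lt_trigone",
    "rt_inferior_horn",
    "lt_inferior_horn",
    "rt_cerebellopontine_angle",
    "lt_cerebellopontine_angle",
    "prepontine_cistern",
    "interpeduncular_cistern",
    "lamina_terminalis_cistern",
    "suprasellar_cistern",
    "quadrigeminal_cistern",
    "rt_ambient_cistern",
    "lt_ambient_cistern",
    "rt_carotid_cistern",
    "lt_carotid_cistern",
    "rt_anterior_sylvian_sulcus",
    "lt_anterior_sylvian_sulcus",
    "rt_sylvian_fossa",
    "lt_sylvian_fossa",
    "rt_posterior_sylvian_sulcus",
    "lt_posterior_sylvian_sulcus",
    "basal_interhemispheric_fissure",
    "upper_interhemispheric_fissure",
    "rt_superior_frontal_sulcus",
    "lt_superior_frontal_sulcus",
    "rt_central_sulcus",
    "lt_central_sulcus",
    "rt_marginal_sulcus",
    "lt_marginal_sulcus"
  ],
  "flow_rois": [
    "foramen_magnum_dorsal",
    "foramen_of_magendie",
    "lower_cerebral_aqueduct",
    "upper_cerebral_aqueduct",
    "lt_foramen_of_monro",
    "rt_foramen_of_monro",
    "prepontine_cistern"
  ],
  "flow_to_ivim": {
    "foramen_magnum_dorsal": "foramen_magnum",
    "foramen_of_magendie": "foramen_of_magendie",
    "lower_cerebral_aqueduct": "upper_4th_ventricle",
    "upper_cerebral_aqueduct": "upper_cerebral_aqueduct",
    "lt_foramen_of_monro": "lt_foramen_of_monro",
    "rt_foramen_of_monro": "rt_foramen_of_monro",
    "prepontine_cistern": "prepontine_cistern"
  }
}
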